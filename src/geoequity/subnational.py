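"""District-level case-study stage: area deprivation and geocoding success.

The bespoke deprivation index standardises each census indicator to a
z-score across districts (after orienting it so larger = more deprived),
averages z-scores within each of six domains (information access, education,
energy, employment, water and sanitation, living conditions), and sums the
six domain means into a composite score — higher = more deprived.  Geocoding
success per district is the exact proportion of facility place-names that
returned an in-region location.  Inequality of success against deprivation
reuses the international RCI/SII machinery with districts ranked
most-deprived first, so a positive RCI means success is concentrated among
the less deprived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import DEPRIVATION_DOMAINS, DistrictRecord, ValidationError
from .inequality import HealthInequalityIndex, InequalityResult


@dataclass
class DeprivationScore:
    district_id: str
    domain_z: dict[str, float]
    total: float


@dataclass
class SuccessRate:
    district_id: str
    rate: float
    n_attempted: int
    n_success: int


class DeprivationIndex(TransformerMixin, BaseEstimator):
    """Domain-averaged z-score deprivation index.

    Parameters
    ----------
    domain_map : mapping indicator -> domain
        Assignment of each census indicator to one of the six domains.
    orientation : mapping indicator -> {+1, -1}
        +1 if a larger raw value means more deprived (e.g. % without
        electricity), -1 otherwise (e.g. literacy rate).  Must be supplied
        explicitly for every indicator; there is no safe default.

    Attributes
    ----------
    mean_, scale_ : pandas.Series
        Per-indicator mean and population standard deviation of the oriented
        values across the fitted districts.
    scores_ : pandas.DataFrame
        Domain means and ``total`` per district.
    """

    def __init__(
        self,
        domain_map: Mapping[str, str],
        orientation: Mapping[str, int],
    ):
        self.domain_map = domain_map
        self.orientation = orientation

    def _frame(self, districts: Sequence[DistrictRecord] | pd.DataFrame) -> pd.DataFrame:
        if isinstance(districts, pd.DataFrame):
            return districts[list(self.domain_map)].astype(float)
        return pd.DataFrame(
            {r.district_id: r.indicators for r in districts}, dtype=float
        ).T.loc[:, list(self.domain_map)]

    def fit(self, districts: Sequence[DistrictRecord] | pd.DataFrame, y=None):
        missing = set(self.domain_map) - set(self.orientation)
        if missing:
            raise ValidationError(f"no orientation supplied for indicators: {sorted(missing)}")
        bad = [d for d in self.domain_map.values() if d not in DEPRIVATION_DOMAINS]
        if bad:
            raise ValidationError(f"unknown deprivation domains: {sorted(set(bad))}")
        X = self._frame(districts)
        if len(X) < 2:
            raise ValidationError("need at least 2 districts")
        oriented = X * pd.Series(self.orientation)[X.columns]
        sd = oriented.std(ddof=0)
        zero = sd.index[sd == 0].tolist()
        if zero:
            raise ValidationError(f"zero variance across districts for indicators: {zero}")
        self.mean_ = oriented.mean()
        self.scale_ = sd
        self.scores_ = self._score(oriented)
        return self

    def _score(self, oriented: pd.DataFrame) -> pd.DataFrame:
        z = (oriented - self.mean_) / self.scale_
        domains = pd.Series(self.domain_map)
        out = {}
        for dom in DEPRIVATION_DOMAINS:
            members = domains.index[domains == dom]
            if len(members):
                out[dom] = z[members].mean(axis=1)
        scores = pd.DataFrame(out)
        scores["total"] = scores.sum(axis=1)
        scores.index.name = "district_id"
        return scores

    def transform(self, districts: Sequence[DistrictRecord] | pd.DataFrame) -> pd.DataFrame:
        X = self._frame(districts)
        oriented = X * pd.Series(self.orientation)[X.columns]
        return self._score(oriented)


def deprivation_index(
    districts: Sequence[DistrictRecord],
    domain_map: Mapping[str, str],
    orientation: Mapping[str, int],
) -> list[DeprivationScore]:
    """Composite deprivation score per district (higher = more deprived)."""
    est = DeprivationIndex(domain_map, orientation).fit(districts)
    out = []
    for district_id, row in est.scores_.iterrows():
        domain_z = {d: row[d] for d in row.index if d != "total"}
        out.append(DeprivationScore(str(district_id), domain_z, float(row["total"])))
    return out


def success_rates(districts: Sequence[DistrictRecord]) -> list[SuccessRate]:
    """Exact geocoding success proportion per district, no smoothing."""
    out = []
    for r in districts:
        if r.n_attempted < 1:
            raise ValidationError(f"district {r.district_id}: n_attempted must be >= 1")
        out.append(
            SuccessRate(r.district_id, r.n_success / r.n_attempted, r.n_attempted, r.n_success)
        )
    return out


def subnational_inequality(
    rates: Sequence[SuccessRate],
    deprivation: Mapping[str, float] | Sequence[DeprivationScore],
    weighting: str = "equal",
    ci_level: float = 0.95,
    deprivation_direction: str = "higher_more_deprived",
    ranking_label: str = "deprivation",
) -> InequalityResult:
    """RCI/SII of geocoding success against area deprivation.

    Districts are ranked most-deprived first.  ``deprivation`` may be the
    bespoke index totals or an external score such as the UNICEF District
    League Table; for the latter pass
    ``deprivation_direction='higher_less_deprived'`` since the DLT measures
    development.  ``weighting='count_weighted'`` weights districts by
    facilities attempted.
    """
    if not isinstance(deprivation, Mapping):
        deprivation = {d.district_id: d.total for d in deprivation}
    ids = [r.district_id for r in rates]
    if set(ids) != set(deprivation):
        raise ValidationError("rates and deprivation cover different district sets")
    if len(ids) < 3:
        raise ValidationError("need at least 3 districts")
    dep = np.asarray([deprivation[i] for i in ids], dtype=float)
    # exposure is affluence: larger = better off, so most-deprived ranks first
    if deprivation_direction == "higher_more_deprived":
        exposure = -dep
    elif deprivation_direction == "higher_less_deprived":
        exposure = dep
    else:
        raise ValidationError(f"unknown deprivation_direction {deprivation_direction!r}")
    y = np.asarray([r.rate for r in rates], dtype=float)
    if weighting == "count_weighted":
        w = np.asarray([r.n_attempted for r in rates], dtype=float)
    elif weighting == "equal":
        w = None
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    est = HealthInequalityIndex(ci_level=ci_level).fit(exposure, y, w)
    return est.result_(ranking_label=ranking_label, outcome_label="geocoding_success_rate")


def in_bbox(
    lon: Sequence[float],
    lat: Sequence[float],
    bbox: tuple[float, float, float, float],
) -> np.ndarray:
    """Boolean containment of (lon, lat) points in (lon_min, lat_min,
    lon_max, lat_max) — an offline stand-in for an in-region check on
    geocoder output."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    lon_min, lat_min, lon_max, lat_max = bbox
    return (lon >= lon_min) & (lon <= lon_max) & (lat >= lat_min) & (lat <= lat_max)
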