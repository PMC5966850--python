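"""Ordinal scoring of provider coverage categories.

Each provider publishes its coverage per country as an ordered category
("address point" down to "locality", "predictive traffic" down to "minimal
street coverage", ...).  Scores here are arbitrary monotone integers —
1-based position in the worst-to-best level list — because everything
downstream is rank-based and only the ordering matters.  Countries with no
published coverage statement score at the worst level, reflecting that
providers list absence ("No service", "unavailable") as a level of its own;
the one exception is the areal-population indicator, which falls back to the
national 2015 population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountryRecord, IndicatorSpec, ValidationError

GOOGLE_COMPONENTS = (
    "google_traffic",
    "google_speed_limits",
    "google_cycling",
    "google_walking",
    "google_driving",
)
_GOOGLE_POINTS = {"good": 2, "approximate": 1, "none": 0}

GEODEMOGRAPHIC_COMPONENTS = ("mosaic_available", "cameo_available", "maptitude_available")


@dataclass
class ScoredIndicator:
    """Per-country numeric scores for one indicator (higher = better
    availability unless ``direction`` says otherwise)."""

    indicator_name: str
    domain: str
    scores: dict[str, float]
    direction: str = "higher_better"
    provenance: dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.indicator_name)


def score_ordinal_indicator(
    records: Sequence[CountryRecord], spec: IndicatorSpec
) -> ScoredIndicator:
    """Score a categorical indicator as the 1-based level position (worst=1)."""
    if spec.kind != "categorical":
        raise ValidationError(f"{spec.name} is not categorical")
    scores, provenance = {}, {}
    for r in records:
        raw = r.indicators.get(spec.name)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            if spec.missing_policy != "worst":
                raise ValidationError(
                    f"{spec.name}: missing value for {r.country_id} and "
                    f"missing_policy={spec.missing_policy!r}"
                )
            scores[r.country_id] = 1.0
            provenance[r.country_id] = "missing_as_worst"
        else:
            scores[r.country_id] = float(spec.score_of(raw))
            provenance[r.country_id] = "observed"
    return ScoredIndicator(spec.name, spec.domain, scores, "higher_better", provenance)


def score_google_travel(
    components: Mapping[str, Mapping[str, str]] | Sequence[CountryRecord],
) -> ScoredIndicator:
    """Composite Google travel-time score in [0,10].

    Five components (traffic layer, speed limits, cycling, walking and
    driving directions) each contribute 2 for good quality/availability,
    1 for approximate, 0 otherwise; the indicator is their sum.
    """
    if not isinstance(components, Mapping):
        components = {
            r.country_id: {c: r.indicators.get(c, "none") for c in GOOGLE_COMPONENTS}
            for r in components
        }
    scores = {}
    for country, comp in components.items():
        total = 0
        for name in GOOGLE_COMPONENTS:
            label = comp.get(name, "none")
            if label not in _GOOGLE_POINTS:
                raise ValidationError(
                    f"google component {name}={label!r} for {country}; "
                    "expected good/approximate/none"
                )
            total += _GOOGLE_POINTS[label]
        scores[country] = float(total)
    return ScoredIndicator("google_travel", "travel", scores)


def score_neighbourhood_disaggregation(
    records: Sequence[CountryRecord],
) -> ScoredIndicator:
    """Mean population per areal unit (lower = finer disaggregation = better).

    Countries without provider data fall back to the national 2015
    population, flagged ``fallback``.
    """
    scores, provenance = {}, {}
    for r in records:
        v = r.indicators.get("mb_population_per_unit")
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            scores[r.country_id] = float(v)
            provenance[r.country_id] = "observed"
        elif r.population_2015 is not None and not np.isnan(r.population_2015):
            scores[r.country_id] = float(r.population_2015)
            provenance[r.country_id] = "fallback"
        else:
            raise ValidationError(
                f"{r.country_id}: neither mb_population_per_unit nor population_2015"
            )
    return ScoredIndicator(
        "mb_population_per_unit", "neighbourhood", scores, "lower_better", provenance
    )


def score_neighbourhood_attributes(records: Sequence[CountryRecord]) -> ScoredIndicator:
    """Count of areal attribute groups; missing counts as zero."""
    scores, provenance = {}, {}
    for r in records:
        v = r.indicators.get("mb_attribute_groups")
        if v is None or (isinstance(v, float) and np.isnan(v)):
            scores[r.country_id] = 0.0
            provenance[r.country_id] = "missing_as_worst"
        else:
            v = float(v)
            if v < 0:
                raise ValidationError(f"{r.country_id}: negative attribute count {v}")
            scores[r.country_id] = v
            provenance[r.country_id] = "observed"
    return ScoredIndicator("mb_attribute_groups", "neighbourhood", scores)


def score_geodemographic_availability(records: Sequence[CountryRecord]) -> ScoredIndicator:
    """Count (0-3) of available geodemographic/demographic products:
    Mosaic Global, CAMEO Worldwide, and Maptitude demographic data."""
    scores = {}
    for r in records:
        total = 0
        for comp in GEODEMOGRAPHIC_COMPONENTS:
            v = r.indicators.get(comp, 0)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                v = 0
            total += int(bool(int(v)))
        scores[r.country_id] = float(total)
    return ScoredIndicator("geodemographic_availability", "neighbourhood", scores)


def score_all(
    records: Sequence[CountryRecord], catalog: Mapping[str, IndicatorSpec]
) -> list[ScoredIndicator]:
    """Score every indicator in the catalog for a country set."""
    out = []
    for spec in catalog.values():
        if spec.kind == "categorical":
            out.append(score_ordinal_indicator(records, spec))
        elif spec.name == "google_travel":
            out.append(score_google_travel(records))
        elif spec.name == "mb_population_per_unit":
            out.append(score_neighbourhood_disaggregation(records))
        elif spec.name == "mb_attribute_groups":
            out.append(score_neighbourhood_attributes(records))
        elif spec.name == "geodemographic_availability":
            out.append(score_geodemographic_availability(records))
        else:
            raise ValidationError(f"no scoring rule for indicator {spec.name}")
    return out


def level_distribution(
    records: Sequence[CountryRecord], spec: IndicatorSpec
) -> pd.DataFrame:
    """Marginal availability summary for one categorical indicator: the
    number and percentage of countries at each coverage level (best first,
    matching how provider coverage tables are usually printed)."""
    scored = score_ordinal_indicator(records, spec)
    ser = pd.Series(
        {c: spec.levels[int(s) - 1] for c, s in scored.scores.items()}, name="level"
    )
    counts = ser.value_counts().reindex(list(spec.levels)[::-1], fill_value=0)
    n = len(records)
    return pd.DataFrame(
        {
            "indicator": spec.name,
            "level": counts.index,
            "n_countries": counts.values,
            "pct": np.round(100.0 * counts.values / n, 1),
        }
    )
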