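"""Shared data model and tabular IO.

Country- and district-level inputs are rectangular CSV tables, one row per
unit.  Records are plain dataclasses; heavier computation downstream works on
:class:`pandas.DataFrame` views built from them.  Validation is strict: a
categorical coverage value outside the declared level set, or a duplicated
unit key, is a hard error rather than a silent coercion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("geoequity")

MORTALITY_COLUMNS = ("mortality_all", "mortality_cmnn", "mortality_ncd", "mortality_inj")

#: The six census domains of the district deprivation index.
DEPRIVATION_DOMAINS = (
    "information_access",
    "education",
    "energy",
    "employment",
    "water_sanitation",
    "living_conditions",
)

RESOURCE_DOMAINS = ("geocoding", "travel", "neighbourhood")


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class IndicatorSpec:
    """Definition of one provider coverage indicator.

    ``levels`` runs from worst to best availability, so the 1-based position
    of a raw category in ``levels`` is its ordinal score.  Numeric indicators
    use ``direction`` instead; ``missing_policy`` says how an absent value is
    treated (``worst`` level, ``fallback_population``, or ``zero``).
    """

    name: str
    domain: str
    kind: str = "categorical"  # categorical | numeric | composite
    levels: Sequence[str] = ()
    direction: str = "higher_better"
    missing_policy: str = "worst"
    components: Mapping[str, dict] = field(default_factory=dict)
    frequency: Mapping[str, int] = field(default_factory=dict)
    reference_quantiles: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.domain not in RESOURCE_DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r} for indicator {self.name}")
        if self.kind == "categorical" and not self.levels:
            raise ValidationError(f"categorical indicator {self.name} has no levels")

    def score_of(self, raw: str) -> int:
        """1-based position of ``raw`` in the worst-to-best level list."""
        try:
            return list(self.levels).index(raw) + 1
        except ValueError:
            raise ValidationError(
                f"value {raw!r} is not a level of indicator {self.name!r}; "
                f"expected one of {list(self.levels)}"
            ) from None


@dataclass
class CountryRecord:
    """One country's mortality outcomes, covariates, and raw coverage values."""

    country_id: str
    name: str = ""
    mortality_all: float = np.nan
    mortality_cmnn: float = np.nan
    mortality_ncd: float = np.nan
    mortality_inj: float = np.nan
    population_2015: float = np.nan
    gdp_per_capita: float | None = None
    internet_users_pct: float | None = None
    indicators: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in MORTALITY_COLUMNS:
            v = getattr(self, col)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValidationError(f"{col} < 0 for country {self.country_id}")
        if self.internet_users_pct is not None and not np.isnan(self.internet_users_pct):
            if not 0 <= self.internet_users_pct <= 100:
                raise ValidationError(
                    f"internet_users_pct out of [0,100] for country {self.country_id}"
                )


@dataclass
class DistrictRecord:
    """One district's census deprivation indicators and geocoding counts."""

    district_id: str
    name: str = ""
    indicators: dict = field(default_factory=dict)
    n_attempted: int = 0
    n_success: int = 0
    dlt_score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= max(self.n_attempted, 0):
            raise ValidationError(
                f"district {self.district_id}: need 0 <= n_success <= n_attempted, "
                f"got {self.n_success}/{self.n_attempted}"
            )


@dataclass
class AnalysisConfig:
    """Pipeline-level options shared across stages."""

    outcome_column: str = "mortality_all"
    ci_level: float = 0.95
    weighting: str = "equal"  # equal | count_weighted
    residual_threshold: float = 2.0
    ci_method: str = "t"  # t | bootstrap
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0,1)")
        if self.weighting not in ("equal", "count_weighted"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_catalog(path: str | Path | None = None) -> dict[str, IndicatorSpec]:
    """Load the indicator catalog (packaged default, or a user-supplied YAML)."""
    if path is None:
        src = resources.files("geoequity").joinpath("data/indicator_catalog.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    catalog = {}
    for name, entry in raw["indicators"].items():
        entry = dict(entry)
        entry.pop("descriptions", None)
        catalog[name] = IndicatorSpec(name=name, **entry)
    return catalog


def _indicator_columns(catalog: Mapping[str, IndicatorSpec]) -> list[str]:
    cols: list[str] = []
    for spec in catalog.values():
        if spec.kind == "composite":
            cols.extend(spec.components)
        else:
            cols.append(spec.name)
    return cols


def read_country_table(
    path: str | Path, spec_catalog: Mapping[str, IndicatorSpec]
) -> list[CountryRecord]:
    """Read a country CSV, validating keys and categorical coverage values.

    Missing cells stay missing (no coercion to a level); a duplicated
    ``country_id`` or a categorical value outside the declared level set is a
    hard error naming the offending row/column.
    """
    df = pd.read_csv(path, dtype={"country_id": str})
    if "country_id" not in df.columns:
        raise ValidationError(f"{path}: no country_id column")
    dup = df["country_id"][df["country_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate country_id: {sorted(set(dup))}")

    for spec in spec_catalog.values():
        if spec.kind != "categorical" or spec.name not in df.columns:
            continue
        col = df[spec.name]
        bad = col.dropna()[~col.dropna().isin(spec.levels)]
        if len(bad):
            row = bad.index[0]
            raise ValidationError(
                f"row {row} ({df.loc[row, 'country_id']}), column {spec.name!r}: "
                f"value {bad.iloc[0]!r} is not in levels {list(spec.levels)}"
            )

    ind_cols = [c for c in _indicator_columns(spec_catalog) if c in df.columns]
    records = []
    for _, row in df.iterrows():
        indicators = {c: row[c] for c in ind_cols if pd.notna(row[c])}
        records.append(
            CountryRecord(
                country_id=row["country_id"],
                name=row.get("name", ""),
                mortality_all=float(row.get("mortality_all", np.nan)),
                mortality_cmnn=float(row.get("mortality_cmnn", np.nan)),
                mortality_ncd=float(row.get("mortality_ncd", np.nan)),
                mortality_inj=float(row.get("mortality_inj", np.nan)),
                population_2015=float(row.get("population_2015", np.nan)),
                gdp_per_capita=(
                    float(row["gdp_per_capita"])
                    if "gdp_per_capita" in row and pd.notna(row["gdp_per_capita"])
                    else None
                ),
                internet_users_pct=(
                    float(row["internet_users_pct"])
                    if "internet_users_pct" in row and pd.notna(row["internet_users_pct"])
                    else None
                ),
                indicators=indicators,
            )
        )
    logger.info("read %d country records from %s", len(records), path)
    return records


def read_district_table(
    path: str | Path, domain_map: Mapping[str, str]
) -> list[DistrictRecord]:
    """Read a district CSV; ``domain_map`` assigns each indicator column to a
    deprivation domain (sidecar contract)."""
    df = pd.read_csv(path, dtype={"district_id": str})
    if "district_id" not in df.columns:
        raise ValidationError(f"{path}: no district_id column")
    dup = df["district_id"][df["district_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate district_id: {sorted(set(dup))}")
    unknown = [d for d in domain_map.values() if d not in DEPRIVATION_DOMAINS]
    if unknown:
        raise ValidationError(f"unknown deprivation domains: {unknown}")
    ind_cols = [c for c in domain_map if c in df.columns]
    missing = sorted(set(domain_map) - set(ind_cols))
    if missing:
        raise ValidationError(f"indicator columns missing from {path}: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DistrictRecord(
                district_id=row["district_id"],
                name=row.get("name", ""),
                indicators={c: float(row[c]) for c in ind_cols},
                n_attempted=int(row["n_attempted"]),
                n_success=int(row["n_success"]),
                dlt_score=(
                    float(row["dlt_score"])
                    if "dlt_score" in row and pd.notna(row["dlt_score"])
                    else None
                ),
            )
        )
    logger.info("read %d district records from %s", len(records), path)
    return records


def country_frame(records: Sequence[CountryRecord]) -> pd.DataFrame:
    """Flatten country records into a DataFrame indexed by country_id."""
    rows = []
    for r in records:
        row = {
            "country_id": r.country_id,
            "name": r.name,
            "mortality_all": r.mortality_all,
            "mortality_cmnn": r.mortality_cmnn,
            "mortality_ncd": r.mortality_ncd,
            "mortality_inj": r.mortality_inj,
            "population_2015": r.population_2015,
            "gdp_per_capita": r.gdp_per_capita,
            "internet_users_pct": r.internet_users_pct,
        }
        row.update(r.indicators)
        rows.append(row)
    return pd.DataFrame(rows).set_index("country_id")


def write_results(records: pd.DataFrame | Sequence, path: str | Path) -> None:
    """Write a result table as CSV with stable column order and >= 6
    significant digits, so write-then-read round-trips numerically."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r for r in records])
    if df.empty:
        raise ValidationError("refusing to write an empty result table")
    df.to_csv(path, index=False, float_format="%.8g")
    logger.info("wrote %d rows to %s", len(df), path)
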