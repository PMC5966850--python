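"""End-to-end stages chaining scoring, indices, inequality and diagnostics.

Each runner consumes validated records and emits the stage's result tables;
the CLI is a thin shell over these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import composite, diagnostics, inequality, scoring, subnational
from .datamodel import (
    MORTALITY_COLUMNS,
    AnalysisConfig,
    CountryRecord,
    DistrictRecord,
    IndicatorSpec,
    ValidationError,
    country_frame,
    write_results,
)

logger = logging.getLogger("geoequity")


def international_analysis(
    records: Sequence[CountryRecord],
    catalog: Mapping[str, IndicatorSpec],
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Score all indicators, build domain/overall indices, compute the
    inequality table over every (ranking variable x mortality outcome) pair,
    and run the outlier/correlation diagnostics.

    Returns a dict of DataFrames: ``scores``, ``indices``, ``inequality``,
    ``outliers``, ``summary``.
    """
    config = config or AnalysisConfig()
    scored = scoring.score_all(records, catalog)
    logger.info("scored %d indicators for %d countries", len(scored), len(records))

    agg = composite.RankAggregationIndex().fit(scored)
    indices = agg.index_

    cf = country_frame(records)
    # ranking variables: per-indicator mid-ranks (direction already applied,
    # larger = better availability) then the domain and overall indices
    data = agg.ranks_.join(indices).join(cf[list(MORTALITY_COLUMNS)])
    ranking_cols = list(agg.ranks_.columns) + list(indices.columns)
    domain_of = dict(agg.domain_of_)
    for col in indices.columns:
        domain_of[col] = col.replace("_index", "")
    table = inequality.inequality_table(
        data,
        ranking_cols,
        [config.outcome_column]
        + [c for c in MORTALITY_COLUMNS if c != config.outcome_column],
        domain_of=domain_of,
        ci_level=config.ci_level,
        ci_method=config.ci_method,
        random_state=config.seed,
    )

    report = diagnostics.log_regression_outliers(
        cf[config.outcome_column], indices["overall_index"], threshold=config.residual_threshold
    )
    corr = diagnostics.covariate_correlations(
        indices["overall_index"], cf["internet_users_pct"], cf["gdp_per_capita"]
    )
    out_frame = report.frame()
    out_frame.insert(1, "index", indices["overall_index"].loc[out_frame["country_id"]].values)
    out_frame.insert(2, "outcome", cf[config.outcome_column].loc[out_frame["country_id"]].values)
    summary = pd.DataFrame(
        [{"slope": report.slope, "intercept": report.intercept, **corr}]
    )
    scores_frame = pd.concat([s.as_series() for s in scored], axis=1)
    scores_frame.index.name = "country_id"
    return {
        "scores": scores_frame,
        "indices": indices,
        "inequality": table,
        "outliers": out_frame,
        "summary": summary,
    }


def subnational_analysis(
    records: Sequence[DistrictRecord],
    domain_map: Mapping[str, str],
    orientation: Mapping[str, int],
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Deprivation scores, geocoding success rates, and the district-level
    inequality rows (bespoke index always; DLT where supplied)."""
    config = config or AnalysisConfig()
    dep = subnational.DeprivationIndex(dict(domain_map), dict(orientation)).fit(records)
    rates = subnational.success_rates(records)
    weighting = "count_weighted" if config.weighting == "count_weighted" else "equal"

    rows = []
    res = subnational.subnational_inequality(
        rates,
        dep.scores_["total"].to_dict(),
        weighting=weighting,
        ci_level=config.ci_level,
        ranking_label="bespoke_deprivation_index",
    )
    rows.append(res)
    if all(r.dlt_score is not None for r in records):
        res = subnational.subnational_inequality(
            rates,
            {r.district_id: r.dlt_score for r in records},
            weighting=weighting,
            ci_level=config.ci_level,
            deprivation_direction="higher_less_deprived",
            ranking_label="dlt_score",
        )
        rows.append(res)
    ineq = pd.DataFrame(
        [
            {
                "ranking_variable": r.ranking_label,
                "rci": r.rci,
                "sii": r.sii,
                "sii_lo": r.sii_ci_lo,
                "sii_hi": r.sii_ci_hi,
                "n": r.n,
            }
            for r in rows
        ]
    )
    rate_frame = pd.DataFrame(
        [
            {
                "district_id": r.district_id,
                "rate": r.rate,
                "n_attempted": r.n_attempted,
                "n_success": r.n_success,
            }
            for r in rates
        ]
    )
    return {
        "deprivation": dep.scores_.reset_index(),
        "success_rates": rate_frame,
        "inequality": ineq,
    }


def write_outputs(outputs: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in outputs.items():
        path = outdir / f"{name}.csv"
        frame = df.reset_index() if df.index.name else df
        write_results(frame, path)
        written.append(path)
    return written
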