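"""Regression diagnostics on the resource index.

Log mortality is regressed on the overall geospatial resource index by OLS;
countries whose externally (leave-one-out) studentised residual exceeds 2 in
absolute value are flagged as availability outliers — both directions, since
interesting outliers include high-availability/high-mortality countries and
low-availability/low-mortality ones.  Pearson correlations of the index with
internet use and GDP per capita are computed on pairwise-complete cases,
reporting n per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.outliers_influence import OLSInfluence

from .datamodel import ValidationError


@dataclass
class OutlierReport:
    slope: float
    intercept: float
    residuals: dict[str, float]
    outliers: list[str]
    threshold: float
    r_internet: float | None = None
    n_internet: int | None = None
    r_gdp: float | None = None
    n_gdp: int | None = None
    fitted: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        ids = list(self.residuals)
        return pd.DataFrame(
            {
                "country_id": ids,
                "fitted": [self.fitted.get(i, np.nan) for i in ids],
                "studentised_residual": [self.residuals[i] for i in ids],
                "is_outlier": [i in set(self.outliers) for i in ids],
            }
        )


class LogLinearOutlierDetector(BaseEstimator):
    """OLS of log outcome on the resource index with studentised-residual
    outlier flagging.

    Parameters
    ----------
    threshold : float, default 2.0
        Flag |t_i| > threshold.
    studentized : {"external", "internal"}
        Leave-one-out (default) or internally studentised residuals.

    Attributes
    ----------
    slope_, intercept_ : float
    residuals_ : ndarray of studentised residuals
    outlier_mask_ : boolean ndarray
    """

    def __init__(self, threshold: float = 2.0, studentized: str = "external"):
        self.threshold = threshold
        self.studentized = studentized

    def fit(self, index: Sequence[float], y: Sequence[float]) -> "LogLinearOutlierDetector":
        index = np.asarray(index, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if index.size < 4:
            raise ValidationError("need n >= 4 for leave-one-out residuals")
        if np.any(y <= 0):
            bad = int(np.flatnonzero(y <= 0)[0])
            raise ValidationError(f"outcome must be > 0 to take logs (unit at position {bad})")
        X = sm.add_constant(index)
        fit = sm.OLS(np.log(y), X).fit()
        self.intercept_, self.slope_ = map(float, fit.params)
        self.fitted_ = np.asarray(fit.fittedvalues)
        # an (essentially) exact fit has no residual scale to studentise
        # against; call every residual zero rather than dividing noise by noise
        resid = np.log(y) - self.fitted_
        scale = max(1.0, float(np.abs(np.log(y)).max()))
        if np.abs(resid).max() <= 1e-10 * scale:
            self.residuals_ = np.zeros_like(resid)
            self.outlier_mask_ = np.zeros_like(resid, dtype=bool)
            return self
        infl = OLSInfluence(fit)
        if self.studentized == "external":
            self.residuals_ = np.asarray(infl.resid_studentized_external)
        elif self.studentized == "internal":
            self.residuals_ = np.asarray(infl.resid_studentized_internal)
        else:
            raise ValidationError(f"unknown studentized option {self.studentized!r}")
        self.outlier_mask_ = np.abs(self.residuals_) > self.threshold
        return self

    def predict(self, index: Sequence[float]) -> np.ndarray:
        """Fitted log outcome at the given index values."""
        return self.intercept_ + self.slope_ * np.asarray(index, dtype=float)


def log_regression_outliers(
    outcome: Mapping[str, float] | pd.Series,
    index: Mapping[str, float] | pd.Series,
    threshold: float = 2.0,
    studentized: str = "external",
) -> OutlierReport:
    """Flag countries with |studentised residual| > ``threshold`` from the
    OLS of log outcome on the overall resource index."""
    outcome = pd.Series(outcome, dtype=float)
    index = pd.Series(index, dtype=float).reindex(outcome.index)
    if index.isna().any():
        raise ValidationError("index missing for some countries")
    nonpos = outcome.index[outcome <= 0].tolist()
    if nonpos:
        raise ValidationError(f"outcome must be > 0 to take logs: {nonpos}")
    est = LogLinearOutlierDetector(threshold=threshold, studentized=studentized).fit(
        index.to_numpy(), outcome.to_numpy()
    )
    ids = list(outcome.index)
    return OutlierReport(
        slope=est.slope_,
        intercept=est.intercept_,
        residuals=dict(zip(ids, est.residuals_)),
        outliers=[i for i, flag in zip(ids, est.outlier_mask_) if flag],
        threshold=threshold,
        fitted=dict(zip(ids, est.fitted_)),
    )


def covariate_correlations(
    index: Mapping[str, float] | pd.Series,
    internet_pct: Mapping[str, float] | pd.Series,
    gdp_per_capita: Mapping[str, float] | pd.Series,
) -> dict:
    """Pearson r of the resource index with internet use and GDP per capita
    on pairwise-complete cases, with per-covariate n and p-values."""
    index = pd.Series(index, dtype=float)
    out: dict = {}
    for key, cov in (("internet", internet_pct), ("gdp", gdp_per_capita)):
        cov = pd.Series(cov, dtype=float).reindex(index.index)
        mask = index.notna() & cov.notna()
        n = int(mask.sum())
        if n < 3:
            raise ValidationError(f"fewer than 3 complete pairs for {key}")
        r, p = stats.pearsonr(index[mask], cov[mask])
        out[f"r_{key}"] = float(r)
        out[f"p_{key}"] = float(p)
        out[f"n_{key}"] = n
    return out
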