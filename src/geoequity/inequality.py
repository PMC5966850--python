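"""Slope index of inequality and relative concentration index.

Units (countries or districts) are ranked by an exposure variable — data
availability or affluence — and assigned fractional (ridit) ranks r in (0,1):
the cumulative-weight midpoint after sorting worst-off first.  Two summary
measures of the outcome gradient across that ranking are computed:

* the relative concentration index, RCI = 2*cov_w(y, r) / mu, a dimensionless
  value in (-1, 1) that is negative when the outcome (e.g. mortality) is
  concentrated at the worst-off end;

* the slope index of inequality, the modelled outcome gap between the
  hypothetical extremes of the ranking, obtained from a weighted
  least-squares fit y = a + b*r and reported as SII = -b, i.e. worst-off end
  minus best-off end.  With this sign convention a health outcome that is
  worse among the data-poor yields a positive SII alongside a negative RCI.

Confidence intervals for the SII use the t distribution on the WLS slope
standard error by default; a seeded case-resampling bootstrap is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import ValidationError


@dataclass
class InequalityResult:
    """RCI and SII (with CI) for one ranking-variable/outcome pair."""

    rci: float
    sii: float
    sii_ci_lo: float
    sii_ci_hi: float
    n: int
    ranking_label: str = ""
    outcome_label: str = ""
    ci_level: float = 0.95


def fractional_ranks(
    exposure: Sequence[float], weights: Sequence[float] | None = None
) -> np.ndarray:
    """Fractional (ridit) ranks in (0,1), worst-off first.

    After sorting ascending by exposure, unit i gets the cumulative-weight
    midpoint (W_<i + w_i/2)/W; tied exposures all receive their tie group's
    midpoint, which keeps the weighted mean of the ranks exactly 0.5.  With
    equal weights and no ties this is the closed form (i - 0.5)/n.
    """
    x = np.asarray(exposure, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 units to rank")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    W = ws.sum()
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    r_sorted = np.empty_like(xs)
    i = 0
    while i < len(xs):
        j = i
        while j < len(xs) and xs[j] == xs[i]:
            j += 1
        r_sorted[i:j] = (cum[i] + (cum[j] - cum[i]) / 2.0) / W
        i = j
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    return r


def concentration_index(
    y: Sequence[float],
    rank: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Relative concentration index 2*cov_w(y, r)/mu against fractional ranks."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = float(np.sum(w * y))
    if mu == 0:
        warnings.warn("constant-zero outcome: concentration index defined as 0")
        return 0.0
    cov = float(np.sum(w * (y - mu) * (r - np.sum(w * r))))
    return 2.0 * cov / mu


def _wls_slope(y: np.ndarray, r: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares of y on r; returns (slope, intercept, SE(slope))."""
    sw = w / w.sum()
    rbar = np.sum(sw * r)
    ybar = np.sum(sw * y)
    sxx = np.sum(sw * (r - rbar) ** 2)
    if sxx == 0:
        raise ValidationError("all fractional ranks identical: slope undefined")
    beta = np.sum(sw * (r - rbar) * (y - ybar)) / sxx
    alpha = ybar - beta * rbar
    n = len(y)
    resid = y - alpha - beta * r
    dof = n - 2
    if dof <= 0:
        raise ValidationError("need n >= 3 for a slope standard error")
    sigma2 = np.sum(sw * resid**2) * n / dof
    se = float(np.sqrt(sigma2 / (n * sxx)))
    return float(beta), float(alpha), se


def slope_index(
    y: Sequence[float],
    rank: Sequence[float],
    weights: Sequence[float] | None = None,
    ci_level: float = 0.95,
    ci_method: str = "t",
    n_boot: int = 1000,
    random_state: int | np.random.Generator | None = None,
    exposure: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Slope index of inequality with CI, reported worst-off minus best-off.

    ``ci_method='t'`` uses SII -/+ t_{1-(1-level)/2, n-2} * SE(b) from the
    WLS fit; ``'bootstrap'`` resamples units with replacement (re-ranking
    each resample when ``exposure`` is supplied) and takes percentile bounds.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(rank, dtype=float)
    if y.size < 3:
        raise ValidationError("need n >= 3 for the slope index")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    beta, _, se = _wls_slope(y, r, w)
    sii = -beta
    if ci_method == "t":
        tcrit = stats.t.ppf(1 - (1 - ci_level) / 2, df=y.size - 2)
        lo, hi = sorted((sii - tcrit * se, sii + tcrit * se))
        return sii, float(lo), float(hi)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(random_state)
        boots = np.empty(n_boot)
        idx_all = np.arange(y.size)
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=y.size, replace=True)
            if exposure is not None:
                try:
                    rb = fractional_ranks(np.asarray(exposure, float)[idx], w[idx])
                except ValidationError:
                    boots[b] = np.nan
                    continue
            else:
                rb = r[idx]
            try:
                beta_b, _, _ = _wls_slope(y[idx], rb, w[idx])
            except ValidationError:
                boots[b] = np.nan
                continue
            boots[b] = -beta_b
        alpha = 1 - ci_level
        lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return sii, float(lo), float(hi)
    raise ValidationError(f"unknown ci_method {ci_method!r}")


class HealthInequalityIndex(BaseEstimator):
    """Estimator computing RCI and SII of an outcome against an exposure.

    Parameters
    ----------
    ci_level : float, default 0.95
        Two-sided confidence level for the SII interval.
    ci_method : {"t", "bootstrap"}
        Analytic t interval on the WLS slope (default) or a seeded
        case-resampling bootstrap.
    n_boot : int, default 1000
        Bootstrap resamples (bootstrap method only).
    random_state : int or Generator, optional
        Seed for the bootstrap.

    Attributes
    ----------
    rank_ : ndarray
        Fractional ranks of the fitted units, worst-off first.
    mu_ : float
        Weighted mean outcome.
    rci_ : float
    sii_, sii_ci_lo_, sii_ci_hi_ : float
    n_ : int
    """

    def __init__(
        self,
        ci_level: float = 0.95,
        ci_method: str = "t",
        n_boot: int = 1000,
        random_state: int | np.random.Generator | None = None,
    ):
        self.ci_level = ci_level
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(
        self,
        exposure: Sequence[float],
        y: Sequence[float],
        sample_weight: Sequence[float] | None = None,
    ) -> "HealthInequalityIndex":
        """Rank units by ``exposure`` (larger = better off) and summarise the
        gradient of ``y`` across the ranking."""
        exposure = np.asarray(exposure, dtype=float)
        y = np.asarray(y, dtype=float)
        if exposure.shape != y.shape:
            raise ValidationError("exposure and y must have the same length")
        if np.any(~np.isfinite(exposure)) or np.any(~np.isfinite(y)):
            raise ValidationError("exposure and y must be finite")
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        self.rank_ = fractional_ranks(exposure, w)
        self.mu_ = float(np.sum(w * y) / np.sum(w))
        self.rci_ = concentration_index(y, self.rank_, w)
        self.sii_, self.sii_ci_lo_, self.sii_ci_hi_ = slope_index(
            y,
            self.rank_,
            w,
            ci_level=self.ci_level,
            ci_method=self.ci_method,
            n_boot=self.n_boot,
            random_state=self.random_state,
            exposure=exposure,
        )
        self.n_ = int(y.size)
        return self

    def result_(self, ranking_label: str = "", outcome_label: str = "") -> InequalityResult:
        return InequalityResult(
            rci=self.rci_,
            sii=self.sii_,
            sii_ci_lo=self.sii_ci_lo_,
            sii_ci_hi=self.sii_ci_hi_,
            n=self.n_,
            ranking_label=ranking_label,
            outcome_label=outcome_label,
            ci_level=self.ci_level,
        )


def inequality_table(
    data: pd.DataFrame,
    ranking_columns: Sequence[str],
    outcome_columns: Sequence[str],
    domain_of: dict[str, str] | None = None,
    weights: Sequence[float] | None = None,
    ci_level: float = 0.95,
    ci_method: str = "t",
    random_state: int | None = None,
) -> pd.DataFrame:
    """One RCI/SII row per (ranking variable x outcome) pair.

    ``data`` holds one unit per row with ranking variables (availability
    scores or indices, larger = better off) and outcomes as columns.
    """
    rows = []
    for rank_col in ranking_columns:
        for out_col in outcome_columns:
            est = HealthInequalityIndex(
                ci_level=ci_level, ci_method=ci_method, random_state=random_state
            ).fit(data[rank_col].to_numpy(), data[out_col].to_numpy(), weights)
            rows.append(
                {
                    "domain": (domain_of or {}).get(rank_col, ""),
                    "indicator": rank_col,
                    "outcome": out_col,
                    "rci": est.rci_,
                    "sii": est.sii_,
                    "sii_lo": est.sii_ci_lo_,
                    "sii_hi": est.sii_ci_hi_,
                    "n": est.n_,
                }
            )
    return pd.DataFrame(rows)
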