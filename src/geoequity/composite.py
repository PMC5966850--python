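"""Composite geospatial resource index by rank aggregation.

Within each of the three domains (geocoding, patient travel, neighbourhood
characterisation) every country is ranked on every indicator, with rank n =
best availability and ties given the mean of the tied positions.  A domain's
index is the country's summed rank divided by the maximum possible summed
rank K*n, landing in (0,1]; the overall index is the sum of the three domain
indices, in (0,3], so that no domain dominates through having more
indicators.  Because only ranks enter, any strictly monotone transformation
of an indicator leaves the index unchanged.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import RESOURCE_DOMAINS, ValidationError
from .scoring import ScoredIndicator


def rank_countries(indicator: ScoredIndicator) -> dict[str, float]:
    """Mid-rank countries on one indicator, rank n = best availability.

    ``lower_better`` indicators (e.g. population per areal unit) are inverted
    before ranking.  Tied scores receive the mean of the tied positions, so
    the ranks always sum to n(n+1)/2.
    """
    if not indicator.scores:
        raise ValidationError(f"{indicator.indicator_name}: empty country set")
    ids = list(indicator.scores)
    values = np.asarray([indicator.scores[c] for c in ids], dtype=float)
    if indicator.direction == "lower_better":
        values = -values
    ranks = rankdata(values, method="average")
    return dict(zip(ids, ranks))


class RankAggregationIndex(TransformerMixin, BaseEstimator):
    """Composite resource index transformer.

    Parameters
    ----------
    domains : sequence of str
        Domain names expected in the input (default: the three resource
        domains).

    Attributes
    ----------
    ranks_ : pandas.DataFrame
        Per-indicator mid-ranks (countries x indicators), rank n = best.
    n_indicators_ : dict
        Indicator count K per domain.
    index_ : pandas.DataFrame
        One column per domain index plus ``overall_index``.
    """

    def __init__(self, domains: Sequence[str] = RESOURCE_DOMAINS):
        self.domains = domains

    def fit(self, X: Sequence[ScoredIndicator], y=None) -> "RankAggregationIndex":
        if not X:
            raise ValidationError("no indicators supplied")
        country_sets = {frozenset(ind.scores) for ind in X}
        if len(country_sets) != 1:
            raise ValidationError("indicators cover mismatched country sets")
        ids = sorted(next(iter(country_sets)))
        rank_cols = {}
        domain_of = {}
        for ind in X:
            if ind.domain not in self.domains:
                raise ValidationError(f"unexpected domain {ind.domain!r}")
            r = rank_countries(ind)
            rank_cols[ind.indicator_name] = [r[c] for c in ids]
            domain_of[ind.indicator_name] = ind.domain
        self.ranks_ = pd.DataFrame(rank_cols, index=pd.Index(ids, name="country_id"))
        self.domain_of_ = domain_of
        self.n_indicators_ = {
            d: sum(1 for v in domain_of.values() if v == d) for d in self.domains
        }
        n = len(ids)
        cols = {}
        for d in self.domains:
            members = [name for name, dom in domain_of.items() if dom == d]
            if not members:
                continue
            k = len(members)
            cols[f"{d}_index"] = self.ranks_[members].sum(axis=1) / (k * n)
        index = pd.DataFrame(cols)
        index["overall_index"] = index.sum(axis=1)
        self.index_ = index
        return self

    def transform(self, X: Sequence[ScoredIndicator] | None = None) -> pd.DataFrame:
        """Return the per-country domain and overall indices."""
        if X is not None and not hasattr(self, "index_"):
            self.fit(X)
        return self.index_


def domain_index(indicators: Sequence[ScoredIndicator]) -> pd.Series:
    """Index for one domain: summed mid-ranks over K indicators / (K*n)."""
    domains = {ind.domain for ind in indicators}
    if len(domains) != 1:
        raise ValidationError(f"indicators span several domains: {sorted(domains)}")
    est = RankAggregationIndex(domains=sorted(domains)).fit(indicators)
    return est.index_[f"{domains.pop()}_index"]


def overall_index(
    geocoding: pd.Series | Mapping[str, float],
    travel: pd.Series | Mapping[str, float],
    neighbourhood: pd.Series | Mapping[str, float],
) -> pd.Series:
    """Sum of the three domain indices per country, in (0,3]."""
    parts = [pd.Series(p, dtype=float) for p in (geocoding, travel, neighbourhood)]
    ids = set(parts[0].index)
    if any(set(p.index) != ids for p in parts[1:]):
        raise ValidationError("domain indices cover mismatched country sets")
    total = parts[0].add(parts[1]).add(parts[2])
    total.name = "overall_index"
    return total


def resource_index(indicators: Sequence[ScoredIndicator]) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`RankAggregationIndex` on all scored
    indicators and return the per-country index table."""
    return RankAggregationIndex().fit(indicators).index_
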