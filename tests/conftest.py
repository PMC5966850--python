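import numpy as np
import pytest

import geoequity as ge


@pytest.fixture(scope="session")
def catalog():
    return ge.load_catalog()


@pytest.fixture(scope="session")
def small_countries(catalog):
    """Frozen 20-country synthetic table used across unit tests."""
    return ge.simulate_countries(ge.CountrySimConfig(n_countries=20, seed=7), catalog)


@pytest.fixture(scope="session")
def district_sim():
    return ge.simulate_districts(ge.DistrictSimConfig(n_districts=10, seed=11))


def make_records(scores_by_country, **extra):
    """Minimal country records carrying an arbitrary indicator mapping."""
    return [
        ge.CountryRecord(country_id=cid, indicators=dict(ind), **extra)
        for cid, ind in scores_by_country.items()
    ]


def brute_force_midranks(values):
    """Pairwise-comparison mid-ranks, rank n = largest value.

    Independent of scipy.stats.rankdata: rank_i = 1 + #{j: v_j < v_i}
    + 0.5 * #{j != i: v_j == v_i}.
    """
    values = np.asarray(values, dtype=float)
    ranks = []
    for i, v in enumerate(values):
        below = np.sum(values < v)
        tied = np.sum(values == v) - 1
        ranks.append(1.0 + below + 0.5 * tied)
    return np.asarray(ranks)
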