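import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geoequity as ge


class TestFractionalRanks:
    def test_equal_weights_closed_form(self):
        r = ge.fractional_ranks([10, 20, 30, 40])
        np.testing.assert_allclose(r, [0.125, 0.375, 0.625, 0.875])

    def test_two_tied_units_share_half(self):
        np.testing.assert_allclose(ge.fractional_ranks([5, 5]), [0.5, 0.5])

    def test_weighted_cumulative_midpoints(self):
        r = ge.fractional_ranks([1, 2], weights=[1, 3])
        np.testing.assert_allclose(r, [0.125, 0.625])

    def test_single_unit_rejected(self):
        with pytest.raises(ge.ValidationError):
            ge.fractional_ranks([1.0])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ge.ValidationError):
            ge.fractional_ranks([1, 2], weights=[1, 0])

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=15),
        st.lists(st.floats(0.1, 10), min_size=2, max_size=15),
    )
    @settings(max_examples=80, deadline=None)
    def test_weighted_mean_is_half(self, exposure, weights):
        m = min(len(exposure), len(weights))
        r = ge.fractional_ranks(exposure[:m], weights[:m])
        w = np.asarray(weights[:m])
        assert np.isclose(np.sum(w * r) / w.sum(), 0.5, atol=1e-12)
        assert np.all((r > 0) & (r < 1))


class TestConcentrationIndex:
    def test_constant_outcome_is_zero(self):
        r = ge.fractional_ranks([1, 2, 3, 4])
        assert ge.concentration_index([7, 7, 7, 7], r) == 0

    def test_ascending_outcome_quarter(self):
        r = ge.fractional_ranks([1, 2, 3, 4])
        assert np.isclose(ge.concentration_index([10, 20, 30, 40], r), 0.25)

    def test_reversed_exposure_negates(self):
        y = [10, 20, 30, 40]
        r_fwd = ge.fractional_ranks([1, 2, 3, 4])
        r_rev = ge.fractional_ranks([4, 3, 2, 1])
        assert np.isclose(
            ge.concentration_index(y, r_fwd), -ge.concentration_index(y, r_rev)
        )

    def test_zero_mean_outcome_warns_and_returns_zero(self):
        r = ge.fractional_ranks([1, 2, 3])
        with pytest.warns(UserWarning):
            assert ge.concentration_index([0, 0, 0], r) == 0.0

    @given(
        st.lists(st.floats(0.1, 100), min_size=4, max_size=10, unique=True),
        st.floats(0.1, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_scale_invariance_and_bound(self, y, const):
        r = ge.fractional_ranks(np.arange(len(y)))
        rci = ge.concentration_index(y, r)
        assert abs(rci) <= 1 + 1e-12
        assert np.isclose(ge.concentration_index(np.asarray(y) * const, r), rci)

    @given(st.lists(st.floats(0.0, 100), min_size=2, max_size=10, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_sum_form(self, y):
        """Equal weights, no ties: 2*cov(y,r)/mu == (2/(n*mu))*sum(y_i r_i) - 1."""
        n = len(y)
        y = np.asarray(y) + 0.5  # keep mu > 0
        r = ge.fractional_ranks(np.arange(n))
        mu = y.mean()
        brute = (2.0 / (n * mu)) * float(np.sum(y * r)) - 1.0
        assert np.isclose(ge.concentration_index(y, r), brute, atol=1e-12)


class TestSlopeIndex:
    def test_constant_outcome_flat(self):
        r = ge.fractional_ranks([1, 2, 3, 4])
        sii, lo, hi = ge.slope_index([5, 5, 5, 5], r)
        assert sii == 0
        assert lo <= 0 <= hi

    def test_noiseless_linear_recovery(self):
        r = ge.fractional_ranks(np.arange(6))
        y = 100 - 50 * r
        sii, lo, hi = ge.slope_index(y, r)
        assert np.isclose(sii, 50.0)
        assert np.isclose(lo, 50.0) and np.isclose(hi, 50.0)

    def test_ascending_outcome_minus_forty(self):
        r = ge.fractional_ranks([1, 2, 3, 4])
        sii, lo, hi = ge.slope_index([10, 20, 30, 40], r)
        assert np.isclose(sii, -40.0)
        assert lo <= sii <= hi

    def test_complete_tie_rejected(self):
        with pytest.raises(ge.ValidationError):
            ge.slope_index([1, 2, 3], [0.5, 0.5, 0.5])

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        exposure = np.arange(30)
        r = ge.fractional_ranks(exposure)
        y = 100 - 40 * r + rng.normal(0, 2, 30)
        sii, lo, hi = ge.slope_index(
            y, r, ci_method="bootstrap", n_boot=400, random_state=5, exposure=exposure
        )
        assert lo < sii < hi
        assert 20 < sii < 60

    @given(
        st.lists(st.floats(1, 100), min_size=4, max_size=12, unique=True),
        st.floats(0.5, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_equivariance_under_outcome_scaling(self, y, const):
        r = ge.fractional_ranks(np.arange(len(y)))
        sii, _, _ = ge.slope_index(y, r)
        sii2, _, _ = ge.slope_index(np.asarray(y) * const, r)
        assert np.isclose(sii2, const * sii, rtol=1e-9)


class TestHealthInequalityIndex:
    def test_fit_populates_attributes(self):
        est = ge.HealthInequalityIndex().fit([1, 2, 3, 4], [40, 30, 20, 10])
        assert est.n_ == 4
        assert est.rci_ < 0  # outcome concentrated at worst-off end
        assert est.sii_ > 0
        assert est.sii_ci_lo_ <= est.sii_ <= est.sii_ci_hi_

    def test_antisymmetry_under_exposure_reversal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 20)
            exposure = rng.normal(size=n)
            y = rng.uniform(1, 10, size=n)
            a = ge.HealthInequalityIndex().fit(exposure, y)
            b = ge.HealthInequalityIndex().fit(-exposure, y)
            assert np.isclose(a.rci_, -b.rci_, atol=1e-10)
            assert np.isclose(a.sii_, -b.sii_, atol=1e-10)

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        exposure = np.array([3, 1, 2, 2, 5, 4], dtype=float)
        y = np.array([1.0, 6.0, 4.0, 5.0, 0.5, 2.0])
        a = ge.HealthInequalityIndex().fit(exposure, y)
        perm = rng.permutation(6)
        b = ge.HealthInequalityIndex().fit(exposure[perm], y[perm])
        assert np.isclose(a.rci_, b.rci_)
        assert np.isclose(a.sii_, b.sii_)

    def test_sklearn_params_round_trip(self):
        est = ge.HealthInequalityIndex(ci_level=0.9, ci_method="bootstrap")
        assert est.get_params()["ci_level"] == 0.9
        est.set_params(ci_level=0.99)
        assert est.ci_level == 0.99


class TestInequalityTable:
    def test_one_row_per_pair(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {f"x{i}": rng.normal(size=12) for i in range(6)}
            | {"y": rng.uniform(1, 5, 12)}
        )
        table = ge.inequality_table(df, [f"x{i}" for i in range(6)], ["y"])
        assert len(table) == 6
        assert set(table.columns) >= {"indicator", "outcome", "rci", "sii", "sii_lo", "sii_hi", "n"}

    def test_duplicate_outcome_gives_identical_rows(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5.0], "y": [5, 4, 3, 2, 1.0]})
        table = ge.inequality_table(df, ["x"], ["y", "y"])
        assert np.isclose(table.loc[0, "rci"], table.loc[1, "rci"])
        assert np.isclose(table.loc[0, "sii"], table.loc[1, "sii"])
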