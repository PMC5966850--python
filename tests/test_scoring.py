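import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import geoequity as ge
from geoequity.composite import domain_index

from .conftest import make_records


class TestOrdinalScoring:
    @pytest.mark.parametrize(
        "raw, expected",
        [("Level 1", 4), ("Level 2", 3), ("Level 3", 2), ("Level 4", 1)],
    )
    def test_esri_levels_score_best_high(self, catalog, raw, expected):
        recs = make_records({"A": {"esri_geocoding": raw}})
        scored = ge.score_ordinal_indicator(recs, catalog["esri_geocoding"])
        assert scored.scores["A"] == expected

    def test_igeolise_three_categories(self, catalog):
        levels = catalog["igeolise_travel"].levels
        recs = make_records({f"C{i}": {"igeolise_travel": lv} for i, lv in enumerate(levels)})
        scored = ge.score_ordinal_indicator(recs, catalog["igeolise_travel"])
        assert [scored.scores[f"C{i}"] for i in range(3)] == [1, 2, 3]

    def test_constant_input_all_equal(self, catalog):
        recs = make_records({f"C{i}": {"tomtom_geocoding": "Street-level"} for i in range(5)})
        scored = ge.score_ordinal_indicator(recs, catalog["tomtom_geocoding"])
        assert set(scored.scores.values()) == {2}

    def test_missing_scored_worst(self, catalog):
        recs = make_records({"A": {}, "B": {"mapbox_geocoding": "Address geocoding"}})
        scored = ge.score_ordinal_indicator(recs, catalog["mapbox_geocoding"])
        assert scored.scores["A"] == 1
        assert scored.provenance["A"] == "missing_as_worst"

    @given(st.permutations(list(range(4))))
    @settings(max_examples=24, deadline=None)
    def test_monotone_in_level_position(self, catalog, perm):
        """A country at a strictly better level never scores lower."""
        levels = catalog["esri_geocoding"].levels
        recs = make_records({f"C{i}": {"esri_geocoding": levels[p]} for i, p in enumerate(perm)})
        scored = ge.score_ordinal_indicator(recs, catalog["esri_geocoding"])
        for i, pi in enumerate(perm):
            for j, pj in enumerate(perm):
                if pi > pj:
                    assert scored.scores[f"C{i}"] > scored.scores[f"C{j}"]


class TestGoogleTravel:
    def test_all_good_is_ten(self):
        comp = {"A": {c: "good" for c in ge.scoring.GOOGLE_COMPONENTS}}
        assert ge.score_google_travel(comp).scores["A"] == 10

    def test_all_absent_is_zero(self):
        comp = {"A": {c: "none" for c in ge.scoring.GOOGLE_COMPONENTS}}
        assert ge.score_google_travel(comp).scores["A"] == 0

    def test_mixed_components_sum(self):
        comp = {
            "A": {
                "google_traffic": "good",
                "google_speed_limits": "approximate",
                "google_cycling": "none",
                "google_walking": "none",
                "google_driving": "none",
            }
        }
        assert ge.score_google_travel(comp).scores["A"] == 3

    def test_unknown_label_rejected(self):
        comp = {"A": {"google_traffic": "excellent"}}
        with pytest.raises(ge.ValidationError, match="google_traffic"):
            ge.score_google_travel(comp)

    @given(
        st.lists(
            st.tuples(*(st.sampled_from(["good", "approximate", "none"]) for _ in range(5))),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_additive(self, combos):
        points = {"good": 2, "approximate": 1, "none": 0}
        comp = {
            f"C{i}": dict(zip(ge.scoring.GOOGLE_COMPONENTS, combo))
            for i, combo in enumerate(combos)
        }
        scored = ge.score_google_travel(comp)
        for i, combo in enumerate(combos):
            s = scored.scores[f"C{i}"]
            assert 0 <= s <= 10
            assert s == sum(points[c] for c in combo)


class TestNeighbourhood:
    def test_disaggregation_fallback_flagged(self):
        recs = [
            ge.CountryRecord("A", indicators={"mb_population_per_unit": 411.0}),
            ge.CountryRecord("B", population_2015=5_000_000.0),
        ]
        scored = ge.score_neighbourhood_disaggregation(recs)
        assert scored.scores["B"] == 5_000_000.0
        assert scored.provenance["B"] == "fallback"
        assert scored.direction == "lower_better"

    def test_disaggregation_missing_both_errors(self):
        with pytest.raises(ge.ValidationError, match="A"):
            ge.score_neighbourhood_disaggregation([ge.CountryRecord("A")])

    def test_finer_units_rank_better(self):
        recs = [
            ge.CountryRecord("fine", indicators={"mb_population_per_unit": 411.0}),
            ge.CountryRecord("coarse", indicators={"mb_population_per_unit": 23_801_400.0}),
        ]
        ranks = ge.rank_countries(ge.score_neighbourhood_disaggregation(recs))
        assert ranks["fine"] > ranks["coarse"]

    def test_attributes_missing_is_zero(self):
        recs = [ge.CountryRecord("A"), ge.CountryRecord("B", indicators={"mb_attribute_groups": 9})]
        scored = ge.score_neighbourhood_attributes(recs)
        assert scored.scores == {"A": 0.0, "B": 9.0}

    def test_attributes_negative_rejected(self):
        recs = [ge.CountryRecord("A", indicators={"mb_attribute_groups": -1})]
        with pytest.raises(ge.ValidationError):
            ge.score_neighbourhood_attributes(recs)

    @pytest.mark.parametrize(
        "flags, expected",
        [((1, 1, 1), 3), ((0, 0, 0), 0), ((1, 0, 0), 1), ((0, 1, 1), 2)],
    )
    def test_geodemographic_count(self, flags, expected):
        mosaic, cameo, mapt = flags
        recs = [
            ge.CountryRecord(
                "A",
                indicators={
                    "mosaic_available": mosaic,
                    "cameo_available": cameo,
                    "maptitude_available": mapt,
                },
            )
        ]
        assert ge.score_geodemographic_availability(recs).scores["A"] == expected


@given(
    scores=st.lists(st.integers(1, 6), min_size=3, max_size=10),
    scale=st.floats(0.5, 20.0),
    shift=st.floats(-5.0, 5.0),
)
@settings(max_examples=60, deadline=None)
def test_monotone_transform_leaves_domain_index_unchanged(scores, scale, shift):
    """Downstream indices are rank-based, so any strictly increasing
    transform of a scored indicator leaves every domain index unchanged."""
    ids = [f"C{i}" for i in range(len(scores))]
    base = ge.ScoredIndicator("x", "geocoding", dict(zip(ids, map(float, scores))))
    transformed = ge.ScoredIndicator(
        "x", "geocoding", {c: scale * s + shift for c, s in base.scores.items()}
    )
    a = domain_index([base])
    b = domain_index([transformed])
    assert np.allclose(a.values, b.values)


def test_level_distribution_percentages(catalog):
    spec = catalog["esri_geocoding"]
    counts = {"Level 1": 42, "Level 2": 16, "Level 3": 51, "Level 4": 74}
    recs = []
    i = 0
    for lv, c in counts.items():
        for _ in range(c):
            recs.append(ge.CountryRecord(f"C{i}", indicators={"esri_geocoding": lv}))
            i += 1
    dist = ge.level_distribution(recs, spec).set_index("level")
    assert dist["n_countries"].sum() == 183
    assert dist.loc["Level 1", "pct"] == 23.0
    assert dist.loc["Level 2", "pct"] == 8.7
    assert dist.loc["Level 3", "pct"] == 27.9
    assert dist.loc["Level 4", "pct"] == 40.4
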