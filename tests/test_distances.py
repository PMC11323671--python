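"""Gower / DTW / combined distance behavior and cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ehrsyneval as ev
from ehrsyneval.data_model import StaticFeature

CHAPTERS = list(ev.CHAPTER_LABELS)
NUM = StaticFeature("age", "numeric", (0.0, 100.0))
CAT = StaticFeature("gender", "categorical", ("M", "F", "unknown"))


class TestGowerComponent:
    def test_numeric_is_range_normalized(self):
        assert ev.gower_component(0.2, 0.7, NUM, value_range=1.0) == pytest.approx(0.5)

    def test_categorical_mismatch_is_one(self):
        assert ev.gower_component("M", "F", CAT) == 1.0

    @pytest.mark.parametrize("x,f,r", [(0.3, NUM, 2.0), ("M", CAT, None)])
    def test_identical_values_are_zero(self, x, f, r):
        assert ev.gower_component(x, x, f, value_range=r) == 0.0

    def test_zero_range_numeric_is_zero(self):
        assert ev.gower_component(5.0, 5.0, NUM, value_range=0.0) == 0.0

    def test_type_mismatch_rejected(self):
        with pytest.raises(TypeError):
            ev.gower_component("old", 3.0, NUM, value_range=1.0)


class TestGowerRecord:
    def test_examples(self, schema):
        ranges = {"age": 82.0}
        a = {"age": 50.0, "gender": "M", "race": "white", "deceased": "no"}
        assert ev.gower_record(a, a, schema, ranges) == 0.0
        b = dict(a, gender="F")
        assert ev.gower_record(a, b, schema, ranges) == pytest.approx(0.25)
        c = {"age": 132.0, "gender": "F", "race": "black", "deceased": "yes"}
        assert ev.gower_record(a, c, schema, ranges) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2), st.integers(0, 1), st.integers(0, 1))
    def test_more_categorical_mismatches_strictly_increase_distance(self, g, r, d):
        """Flipping one extra categorical feature strictly increases the distance."""
        schema = ev.default_schema()
        ranges = {"age": 82.0}
        a = {"age": 50.0, "gender": "M", "race": "white", "deceased": "no"}
        alts = {"gender": ["M", "F", "unknown"], "race": ["white", "black"],
                "deceased": ["no", "yes"]}
        b = {"age": 50.0, "gender": alts["gender"][g], "race": alts["race"][r],
             "deceased": alts["deceased"][d]}
        base = ev.gower_record(a, b, schema, ranges)
        worse = dict(b)
        for name in ("gender", "race", "deceased"):
            if worse[name] == a[name]:
                worse[name] = [v for v in alts[name] if v != a[name]][0]
                assert ev.gower_record(a, worse, schema, ranges) > base
                break


class TestDtw:
    def test_identical_sequences_zero(self):
        assert ev.dtw_gower(["circulatory", "mental"], ["circulatory", "mental"]) == 0.0

    def test_repeat_alignment_costs_nothing(self):
        # (1,1)(2,1)(3,2) aligns the doubled chapter for free
        a = ["circulatory", "circulatory", "respiratory"]
        b = ["circulatory", "respiratory"]
        assert ev.dtw_gower(a, b) == 0.0

    def test_single_mismatch_geometric_scaling(self):
        a = ["circulatory", "respiratory"]
        b = ["respiratory", "respiratory"]
        assert ev.dtw_gower(a, b) == pytest.approx(1.0 / np.sqrt(4))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ev.dtw_gower([], ["circulatory"])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.sampled_from(CHAPTERS), min_size=1, max_size=8),
        st.lists(st.sampled_from(CHAPTERS), min_size=1, max_size=8),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        d = ev.dtw_gower(a, b)
        assert d >= 0.0
        assert d == pytest.approx(ev.dtw_gower(b, a), abs=1e-12)
        assert ev.dtw_gower(a, a) == 0.0


class TestCombined:
    def test_weighted_average_formula(self, schema):
        ranges = {"age": 100.0}
        # static distance 0.5 (two of four features differ), sequence distance 1.0
        a = ({"age": 10.0, "gender": "M", "race": "white", "deceased": "no"},
             ["circulatory"])
        b = ({"age": 10.0, "gender": "F", "race": "black", "deceased": "no"},
             ["respiratory"])
        got = ev.combined_distance(a, b, schema, ranges)  # default weight 1/5
        assert got == pytest.approx(0.2 * 1.0 + 0.8 * 0.5)

    def test_zero_weight_reduces_to_static_gower(self, schema):
        ranges = {"age": 100.0}
        a = ({"age": 0.0, "gender": "M", "race": "white", "deceased": "no"},
             ["circulatory"])
        b = ({"age": 50.0, "gender": "M", "race": "white", "deceased": "no"},
             ["respiratory", "mental"])
        got = ev.combined_distance(a, b, schema, ranges, weight_seq=0.0)
        assert got == pytest.approx(ev.gower_record(a[0], b[0], schema, ranges))

    def test_identical_records_zero(self, schema):
        a = ({"age": 4.0, "gender": "F", "race": "white", "deceased": "no"},
             ["mental", "mental"])
        assert ev.combined_distance(a, a, schema, {"age": 10.0}) == 0.0

    def test_weight_out_of_range(self, schema):
        a = ({"age": 4.0, "gender": "F", "race": "white", "deceased": "no"}, ["mental"])
        with pytest.raises(ValueError):
            ev.combined_distance(a, a, schema, {"age": 10.0}, weight_seq=1.5)


class TestPairwiseMatrix:
    def test_single_record_pool(self, tiny_dataset):
        one = tiny_dataset.subset(["a"])
        dm = ev.pairwise_matrix([one])
        assert dm.combined.shape == (1, 1) and dm.combined[0, 0] == 0.0

    def test_matches_elementwise_combined_distance(self, tiny_dataset, schema):
        dm = ev.pairwise_matrix([tiny_dataset])
        ranges = ev.pooled_ranges([tiny_dataset], schema)
        ids = dm.ids
        for i in range(3):
            for j in range(3):
                a = (tiny_dataset.static.loc[ids[i]].to_dict(), tiny_dataset.sequences[ids[i]])
                b = (tiny_dataset.static.loc[ids[j]].to_dict(), tiny_dataset.sequences[ids[j]])
                expected = ev.combined_distance(a, b, schema, ranges)
                assert dm.combined[i, j] == pytest.approx(expected, abs=1e-6)

    def test_symmetric_with_origin_tags(self, small_cohort):
        a, b = ev.split_holdout(small_cohort, 0.5, seed=3)
        dm = ev.pairwise_matrix([a, b.copy(origin_tag="synthetic")])
        assert np.array_equal(dm.combined, dm.combined.T)
        assert dm.origins.count("synthetic") == b.n_patients

    def test_jitted_kernel_matches_reference_dtw(self, small_cohort):
        sub = small_cohort.subset(small_cohort.patient_ids[:25])
        dm = ev.pairwise_matrix([sub])
        seqs = [sub.sequences[p] for p in dm.ids]
        for i in range(0, 25, 5):
            for j in range(i + 1, 25, 7):
                assert dm.seq_part[i, j] == pytest.approx(
                    ev.dtw_gower(seqs[i], seqs[j]), abs=1e-9
                )
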