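"""Schema, ICD-9 chapter encoding, CSV round-trips and missing-value handling."""

import numpy as np
import pandas as pd
import pytest

import ehrsyneval as ev
from ehrsyneval.data_model import OMITTED, UNMAPPED, StaticFeature


class TestChapterMap:
    def test_fourteen_retained_labels(self):
        assert len(ev.DEFAULT_CHAPTER_MAP.retained_labels) == 14
        assert len(ev.CHAPTER_LABELS) == 14

    def test_omitted_chapters_are_the_rare_three(self):
        assert ev.DEFAULT_CHAPTER_MAP.omitted == {"pregnancy", "congenital", "perinatal"}

    @pytest.mark.parametrize(
        "code,expected",
        [
            ("410", "circulatory"),  # acute myocardial infarction, 390-459
            ("410.71", "circulatory"),
            ("4109", "circulatory"),
            ("001", "infectious"),
            ("0389", "infectious"),  # septicemia, leading zeros
            ("139", "infectious"),
            ("140", "neoplasms"),
            ("239", "neoplasms"),
            ("250", "endocrine"),
            ("285", "blood"),
            ("296", "mental"),
            ("345", "nervous"),
            ("389", "nervous"),
            ("460", "respiratory"),
            ("531", "digestive"),
            ("584", "genitourinary"),
            ("682", "skin"),
            ("715", "musculoskeletal"),
            ("780", "symptoms"),
            ("800", "injury"),
            ("999", "injury"),
            ("650", OMITTED),  # pregnancy/childbirth chapter is excluded
            ("630", OMITTED),
            ("745", OMITTED),  # congenital anomalies
            ("765", OMITTED),  # perinatal conditions
            ("V10", UNMAPPED),  # supplementary V codes fall outside 001-999
            ("E812", UNMAPPED),
            ("garbage", UNMAPPED),
            ("0", UNMAPPED),
        ],
    )
    def test_icd9_encoding(self, code, expected):
        assert ev.encode_icd9_to_chapter(code) == expected

    def test_empty_code_rejected(self):
        with pytest.raises(ValueError):
            ev.encode_icd9_to_chapter("")


class TestSchema:
    def test_categorical_feature_requires_unknown_category(self):
        with pytest.raises(ValueError, match="unknown"):
            StaticFeature("race", "categorical", ("white", "black"))

    def test_sequence_vocabulary_must_have_14_labels(self, schema):
        with pytest.raises(ValueError, match="14"):
            ev.FeatureSchema(
                static_features=schema.static_features,
                chapter_labels=ev.CHAPTER_LABELS[:13],
            )


class TestDatasetValidation:
    def test_empty_sequence_rejected(self, schema, tiny_dataset):
        seqs = {k: list(v) for k, v in tiny_dataset.sequences.items()}
        seqs["a"] = []
        with pytest.raises(ValueError, match="empty"):
            ev.LongitudinalDataset(schema=schema, static=tiny_dataset.static, sequences=seqs)

    def test_id_mismatch_rejected(self, schema, tiny_dataset):
        seqs = dict(tiny_dataset.sequences)
        del seqs["c"]
        with pytest.raises(ValueError, match="mismatch"):
            ev.LongitudinalDataset(schema=schema, static=tiny_dataset.static, sequences=seqs)

    def test_unknown_chapter_rejected(self, schema, tiny_dataset):
        seqs = {k: list(v) for k, v in tiny_dataset.sequences.items()}
        seqs["a"] = ["circulatory", "pregnancy", "circulatory", "mental", "injury"]
        with pytest.raises(ValueError, match="unknown chapter"):
            ev.LongitudinalDataset(schema=schema, static=tiny_dataset.static, sequences=seqs)


class TestIO:
    def test_round_trip_is_identity(self, tiny_dataset, schema, tmp_path):
        ev.save_dataset(tiny_dataset, tmp_path / "s.csv", tmp_path / "q.csv")
        back = ev.load_dataset(tmp_path / "s.csv", tmp_path / "q.csv", schema)
        assert back.n_patients == 3
        assert sorted(back.lengths()) == [5, 6, 7]
        assert back.sequences == tiny_dataset.sequences
        pd.testing.assert_frame_equal(back.static, tiny_dataset.static, check_like=True)

    def test_save_load_save_is_stable(self, tiny_dataset, schema, tmp_path):
        ev.save_dataset(tiny_dataset, tmp_path / "s1.csv", tmp_path / "q1.csv")
        back = ev.load_dataset(tmp_path / "s1.csv", tmp_path / "q1.csv", schema)
        ev.save_dataset(back, tmp_path / "s2.csv", tmp_path / "q2.csv")
        assert (tmp_path / "s1.csv").read_text() == (tmp_path / "s2.csv").read_text()
        assert (tmp_path / "q1.csv").read_text() == (tmp_path / "q2.csv").read_text()

    def test_omitted_chapter_row_fails_loading(self, tiny_dataset, schema, tmp_path):
        ev.save_dataset(tiny_dataset, tmp_path / "s.csv", tmp_path / "q.csv")
        seq = pd.read_csv(tmp_path / "q.csv")
        seq.loc[0, "chapter"] = "pregnancy"
        seq.to_csv(tmp_path / "q.csv", index=False)
        with pytest.raises(ValueError, match="pregnancy"):
            ev.load_dataset(tmp_path / "s.csv", tmp_path / "q.csv", schema)

    def test_noncontiguous_steps_fail_loading(self, tiny_dataset, schema, tmp_path):
        ev.save_dataset(tiny_dataset, tmp_path / "s.csv", tmp_path / "q.csv")
        seq = pd.read_csv(tmp_path / "q.csv")
        seq.loc[seq.index[-1], "step"] = 99
        seq.to_csv(tmp_path / "q.csv", index=False)
        with pytest.raises(ValueError, match="contiguous"):
            ev.load_dataset(tmp_path / "s.csv", tmp_path / "q.csv", schema)

    def test_missing_id_fails_loading(self, tiny_dataset, schema, tmp_path):
        ev.save_dataset(tiny_dataset, tmp_path / "s.csv", tmp_path / "q.csv")
        static = pd.read_csv(tmp_path / "s.csv")
        static[1:].to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="missing"):
            ev.load_dataset(tmp_path / "s.csv", tmp_path / "q.csv", schema)


class TestMissingEncoding:
    def _with_missing_race(self, tiny_dataset, n_missing=1):
        static = tiny_dataset.static.copy()
        static.iloc[:n_missing, static.columns.get_loc("race")] = np.nan
        return ev.LongitudinalDataset(
            schema=tiny_dataset.schema, static=static, sequences=tiny_dataset.sequences
        )

    def test_absent_race_becomes_unknown(self, tiny_dataset):
        ds = self._with_missing_race(tiny_dataset)
        out = ev.apply_missing_encoding(ds)
        assert out.static["race"].iloc[0] == "unknown"
        # untouched rows keep their values
        assert list(out.static["race"].iloc[1:]) == list(tiny_dataset.static["race"].iloc[1:])

    def test_unknown_count_matches_missing_count(self, tiny_dataset):
        ds = self._with_missing_race(tiny_dataset, n_missing=2)
        before = (tiny_dataset.static["race"] == "unknown").sum()
        out = ev.apply_missing_encoding(ds)
        assert (out.static["race"] == "unknown").sum() == before + 2
        assert not out.static["race"].isna().any()

    def test_clean_dataset_unchanged(self, tiny_dataset):
        out = ev.apply_missing_encoding(tiny_dataset)
        assert out.equals(tiny_dataset)

    def test_absent_age_is_an_error(self, tiny_dataset):
        static = tiny_dataset.static.copy()
        static.iloc[0, static.columns.get_loc("age")] = np.nan
        ds = ev.LongitudinalDataset(
            schema=tiny_dataset.schema, static=static, sequences=tiny_dataset.sequences
        )
        with pytest.raises(ValueError, match="age"):
            ev.apply_missing_encoding(ds)
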