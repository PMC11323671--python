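"""Longitudinal EHR data structures, schema, CSV I/O and ICD-9 chapter encoding.

A longitudinal record here is a row of static patient attributes (mixed
numeric/categorical, with missingness encoded as the reserved category
``"unknown"``) plus a single variable-length sequence of diagnosis
chapters.  Diagnoses are coded at the level of ICD-9 chapters: of the 17
numeric-code chapters, the three that are essentially absent in an
ischaemic-heart-disease cohort (pregnancy/childbirth, congenital
anomalies, perinatal conditions) are dropped, leaving 14 classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

UNKNOWN = "unknown"

#: Sentinel returns of :func:`encode_icd9_to_chapter`.
OMITTED = "__OMITTED__"
UNMAPPED = "__UNMAPPED__"


# ---------------------------------------------------------------------------
# ICD-9 chapter map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChapterMap:
    """The 17 numeric-code ICD-9 chapters with their code ranges.

    ``omitted`` names the three chapters excluded from sequences; the
    remaining 14 labels are the sequence vocabulary.
    """

    chapters: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    omitted: frozenset[str]

    @property
    def retained_labels(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chapters if name not in self.omitted)

    def __post_init__(self) -> None:
        if len(self.chapters) != 17:
            raise ValueError(f"expected 17 ICD-9 chapters, got {len(self.chapters)}")
        if len(self.retained_labels) != 14:
            raise ValueError("retained chapter count must be 14")


#: ICD-9 chapter code ranges (three-digit category codes).
ICD9_CHAPTERS: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = (
    ("infectious", ((1, 139),)),
    ("neoplasms", ((140, 239),)),
    ("endocrine", ((240, 279),)),
    ("blood", ((280, 289),)),
    ("mental", ((290, 319),)),
    ("nervous", ((320, 389),)),
    ("circulatory", ((390, 459),)),
    ("respiratory", ((460, 519),)),
    ("digestive", ((520, 579),)),
    ("genitourinary", ((580, 629),)),
    ("pregnancy", ((630, 679),)),
    ("skin", ((680, 709),)),
    ("musculoskeletal", ((710, 739),)),
    ("congenital", ((740, 759),)),
    ("perinatal", ((760, 779),)),
    ("symptoms", ((780, 799),)),
    ("injury", ((800, 999),)),
)

DEFAULT_CHAPTER_MAP = ChapterMap(
    chapters=ICD9_CHAPTERS,
    omitted=frozenset({"pregnancy", "congenital", "perinatal"}),
)

#: The 14 retained chapter labels, in chapter order.
CHAPTER_LABELS: tuple[str, ...] = DEFAULT_CHAPTER_MAP.retained_labels


def encode_icd9_to_chapter(code: str, chapter_map: ChapterMap = DEFAULT_CHAPTER_MAP) -> str:
    """Map an ICD-9 code string to its chapter label.

    Returns the chapter label for numeric codes 001-999, the sentinel
    :data:`OMITTED` for codes in an excluded chapter, and :data:`UNMAPPED`
    for V/E supplementary codes or anything unparseable.  Codes may carry
    sub-category digits with or without a dot ("410.71", "4109").
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError("ICD-9 code must be a non-empty string")
    code = code.strip().upper()
    if code[0] in ("V", "E"):
        return UNMAPPED
    head = code.split(".")[0][:3]
    try:
        num = int(head)
    except ValueError:
        return UNMAPPED
    if not 1 <= num <= 999:
        return UNMAPPED
    for name, ranges in chapter_map.chapters:
        for lo, hi in ranges:
            if lo <= num <= hi:
                return OMITTED if name in chapter_map.omitted else name
    return UNMAPPED  # pragma: no cover - ranges tile 1..999


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaticFeature:
    name: str
    kind: str  # "numeric" | "categorical"
    #: categories (tuple of str) for categorical, (min, max) range for numeric
    domain: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical" and UNKNOWN not in self.domain:
            raise ValueError(
                f"categorical feature {self.name!r} must include the "
                f"reserved {UNKNOWN!r} category"
            )


@dataclass(frozen=True)
class FeatureSchema:
    """Schema of a longitudinal dataset: static features + one chapter sequence."""

    static_features: tuple[StaticFeature, ...]
    sequence_feature: str = "chapter"
    chapter_labels: tuple[str, ...] = CHAPTER_LABELS
    id_field: str = "patient_id"

    def __post_init__(self) -> None:
        if len(self.chapter_labels) != 14:
            raise ValueError("sequence category set must have exactly 14 labels")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.static_features)

    def feature(self, name: str) -> StaticFeature:
        for f in self.static_features:
            if f.name == name:
                return f
        raise KeyError(name)


def default_schema() -> FeatureSchema:
    """Schema of the reference cohort: age, gender, race, deceased + chapters."""
    return FeatureSchema(
        static_features=(
            StaticFeature("age", "numeric", (18.0, 100.0)),
            StaticFeature("gender", "categorical", ("M", "F", UNKNOWN)),
            StaticFeature(
                "race",
                "categorical",
                ("white", "black", "hispanic", "asian", "other", UNKNOWN),
            ),
            StaticFeature("deceased", "categorical", ("no", "yes", UNKNOWN)),
        ),
    )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalDataset:
    """Static attribute table plus one chapter sequence per patient.

    ``static`` is indexed by patient id (one row per patient); ``sequences``
    maps each patient id to its ordered chapter list.  ``origin_tag`` labels
    where the records came from ("real", "synthetic", ...).
    """

    schema: FeatureSchema
    static: pd.DataFrame
    sequences: dict[str, list[str]]
    origin_tag: str = "real"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def patient_ids(self) -> list[str]:
        return list(self.static.index)

    @property
    def n_patients(self) -> int:
        return len(self.static)

    def lengths(self) -> np.ndarray:
        return np.array([len(self.sequences[i]) for i in self.patient_ids])

    def validate(self) -> None:
        ids = list(self.static.index)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in static table")
        if set(ids) != set(self.sequences):
            missing = set(ids) ^ set(self.sequences)
            raise ValueError(f"static/sequence patient id mismatch: {sorted(missing)[:5]}")
        chapters = set(self.schema.chapter_labels)
        for pid, seq in self.sequences.items():
            if len(seq) < 1:
                raise ValueError(f"patient {pid!r} has an empty sequence")
            bad = set(seq) - chapters
            if bad:
                raise ValueError(f"patient {pid!r} has unknown chapter labels {sorted(bad)}")
        for f in self.schema.static_features:
            if f.name not in self.static.columns:
                raise ValueError(f"static table missing feature {f.name!r}")

    def subset(self, ids: Sequence[str], origin_tag: str | None = None) -> "LongitudinalDataset":
        ids = list(ids)
        return LongitudinalDataset(
            schema=self.schema,
            static=self.static.loc[ids].copy(),
            sequences={i: list(self.sequences[i]) for i in ids},
            origin_tag=self.origin_tag if origin_tag is None else origin_tag,
        )

    def copy(self, origin_tag: str | None = None) -> "LongitudinalDataset":
        return self.subset(self.patient_ids, origin_tag=origin_tag)

    def equals(self, other: "LongitudinalDataset") -> bool:
        return (
            self.schema == other.schema
            and self.static.equals(other.static)
            and self.sequences == other.sequences
            and self.origin_tag == other.origin_tag
        )


def concat_datasets(a: LongitudinalDataset, b: LongitudinalDataset) -> LongitudinalDataset:
    """Pool two id-disjoint datasets (schemas must match)."""
    if a.schema != b.schema:
        raise ValueError("cannot pool datasets with different schemas")
    overlap = set(a.patient_ids) & set(b.patient_ids)
    if overlap:
        raise ValueError(f"patient ids overlap between datasets: {sorted(overlap)[:5]}")
    return LongitudinalDataset(
        schema=a.schema,
        static=pd.concat([a.static, b.static]),
        sequences={**a.sequences, **b.sequences},
        origin_tag=f"{a.origin_tag}+{b.origin_tag}",
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(
    static_path,
    sequence_path,
    schema: FeatureSchema,
    origin_tag: str = "real",
) -> LongitudinalDataset:
    """Read a dataset from the two-CSV layout.

    ``static_path``: one row per patient, columns ``id_field`` + static
    features.  ``sequence_path``: long format with columns
    (``id_field``, ``step``, sequence feature), steps contiguous from 1.
    """
    static = pd.read_csv(static_path, dtype={schema.id_field: str})
    if schema.id_field not in static.columns:
        raise ValueError(f"static file lacks id column {schema.id_field!r}")
    static = static.set_index(schema.id_field)
    for f in schema.static_features:
        if f.name not in static.columns:
            raise ValueError(f"static file lacks feature column {f.name!r}")
        if f.kind == "numeric":
            static[f.name] = static[f.name].astype(float)
        else:
            static[f.name] = static[f.name].astype(str)

    seq_df = pd.read_csv(sequence_path, dtype={schema.id_field: str})
    for col in (schema.id_field, "step", schema.sequence_feature):
        if col not in seq_df.columns:
            raise ValueError(f"sequence file lacks column {col!r}")

    chapters = set(schema.chapter_labels)
    sequences: dict[str, list[str]] = {}
    for pid, grp in seq_df.groupby(schema.id_field, sort=False):
        grp = grp.sort_values("step")
        steps = grp["step"].to_numpy()
        if not np.array_equal(steps, np.arange(1, len(steps) + 1)):
            raise ValueError(f"patient {pid!r}: steps not contiguous from 1")
        seq = [str(c) for c in grp[schema.sequence_feature]]
        bad = set(seq) - chapters
        if bad:
            raise ValueError(f"patient {pid!r}: unknown chapter labels {sorted(bad)}")
        sequences[pid] = seq

    static_ids, seq_ids = set(static.index), set(sequences)
    if static_ids != seq_ids:
        missing = sorted(static_ids ^ seq_ids)
        raise ValueError(f"patient ids missing from one file: {missing[:5]}")

    return LongitudinalDataset(
        schema=schema,
        static=static,
        sequences=sequences,
        origin_tag=origin_tag,
    )


def save_dataset(dataset: LongitudinalDataset, static_path, sequence_path) -> None:
    """Write the two-CSV layout read back by :func:`load_dataset`."""
    dataset.static.to_csv(static_path, index_label=dataset.schema.id_field)
    rows = []
    for pid in dataset.patient_ids:
        for t, chap in enumerate(dataset.sequences[pid], start=1):
            rows.append((pid, t, chap))
    pd.DataFrame(
        rows, columns=[dataset.schema.id_field, "step", dataset.schema.sequence_feature]
    ).to_csv(sequence_path, index=False)


# ---------------------------------------------------------------------------
# Missing-value handling
# ---------------------------------------------------------------------------

def apply_missing_encoding(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Replace absent categorical static values with the "unknown" category.

    Absent numeric values are an error: age is required for every patient,
    and missingness-as-category has no numeric analogue here.
    """
    static = dataset.static.copy()
    for f in dataset.schema.static_features:
        col = static[f.name]
        if f.kind == "numeric":
            if col.isna().any():
                bad = list(static.index[col.isna()])[:5]
                raise ValueError(f"numeric feature {f.name!r} has absent values (e.g. {bad})")
        else:
            absent = col.isna() | col.astype(str).str.strip().isin(("", "nan", "None", "NA"))
            static.loc[absent, f.name] = UNKNOWN
    return LongitudinalDataset(
        schema=dataset.schema,
        static=static,
        sequences={i: list(s) for i, s in dataset.sequences.items()},
        origin_tag=dataset.origin_tag,
    )
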