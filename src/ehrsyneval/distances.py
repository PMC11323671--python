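"""Mixed-type distances for longitudinal records.

Static attributes are compared with Gower distance (range-normalized
absolute difference for numerics, 0/1 mismatch for categoricals, averaged
over features).  Variable-length chapter sequences are compared with
dynamic time warping under a Gower local cost (0/1 for the single
categorical chapter feature), where the optimal alignment is monotone,
continuous and anchored at both endpoints, and the cumulative cost is
scaled by the geometric mean of the two sequence lengths.  The combined
record distance averages the two parts with the whole sequence counting
as one additional feature by default.

Numeric Gower ranges are always computed over the pooled (real and
synthetic) data so distances are comparable across origins.  DTW does not
satisfy the triangle inequality; no metric claim is made beyond symmetry,
non-negativity and identity of indiscernibles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .data_model import FeatureSchema, LongitudinalDataset, StaticFeature

__all__ = [
    "DistanceMatrix",
    "gower_component",
    "gower_record",
    "dtw_gower",
    "combined_distance",
    "pairwise_matrix",
    "pooled_ranges",
    "default_sequence_weight",
]


# ---------------------------------------------------------------------------
# Gower distance on static records
# ---------------------------------------------------------------------------

def gower_component(x, y, feature: StaticFeature, value_range: float | None = None):
    """Single-feature Gower distance in [0, 1].

    Numeric: |x - y| / range (a zero pooled range contributes 0, the
    feature is constant).  Categorical: 0 if equal else 1.
    """
    if feature.kind == "numeric":
        if not isinstance(x, (int, float, np.floating, np.integer)) or not isinstance(
            y, (int, float, np.floating, np.integer)
        ):
            raise TypeError(f"numeric feature {feature.name!r} got non-numeric values")
        if value_range is None:
            raise ValueError(f"numeric feature {feature.name!r} needs a pooled range")
        if value_range == 0:
            return 0.0
        return abs(float(x) - float(y)) / float(value_range)
    if isinstance(x, (int, float, np.floating)) or isinstance(y, (int, float, np.floating)):
        raise TypeError(f"categorical feature {feature.name!r} got numeric values")
    return 0.0 if x == y else 1.0


def gower_record(
    a: Mapping, b: Mapping, schema: FeatureSchema, ranges: Mapping[str, float]
) -> float:
    """Unweighted mean of per-feature Gower components over the static schema."""
    comps = []
    for f in schema.static_features:
        if f.name not in a or f.name not in b:
            raise ValueError(f"record lacks feature {f.name!r}")
        comps.append(gower_component(a[f.name], b[f.name], f, ranges.get(f.name)))
    return float(np.mean(comps))


def pooled_ranges(
    datasets: Sequence[LongitudinalDataset], schema: FeatureSchema
) -> dict[str, float]:
    """Numeric feature ranges over the pooled data (the Gower denominator)."""
    ranges: dict[str, float] = {}
    for f in schema.static_features:
        if f.kind != "numeric":
            continue
        vals = np.concatenate([d.static[f.name].to_numpy(float) for d in datasets])
        ranges[f.name] = float(vals.max() - vals.min())
    return ranges


# ---------------------------------------------------------------------------
# DTW with Gower local cost on chapter sequences
# ---------------------------------------------------------------------------

def dtw_gower(seq_a: Sequence[str], seq_b: Sequence[str]) -> float:
    """DTW distance between two chapter sequences, geometric-mean scaled.

    Cumulative 0/1 local cost of the optimal monotone, continuous,
    endpoint-anchored alignment (classic diagonal/up/right step pattern,
    no warping window), divided by sqrt(len_a * len_b).
    """
    la, lb = len(seq_a), len(seq_b)
    if la == 0 or lb == 0:
        raise ValueError("sequences must be non-empty")
    cost = np.not_equal(
        np.asarray(seq_a, dtype=object)[:, None], np.asarray(seq_b, dtype=object)[None, :]
    ).astype(float)
    D = np.full((la + 1, lb + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            D[i, j] = cost[i - 1, j - 1] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[la, lb]) / float(np.sqrt(la * lb))


@njit(cache=True)
def _dtw_pairwise_int(codes, lengths):  # pragma: no cover - exercised via wrapper
    n = codes.shape[0]
    tmax = codes.shape[1]
    out = np.zeros((n, n))
    prev = np.empty(tmax + 1)
    cur = np.empty(tmax + 1)
    for i in range(n):
        la = lengths[i]
        for j in range(i + 1, n):
            lb = lengths[j]
            for c in range(lb + 1):
                prev[c] = np.inf
            prev[0] = 0.0
            for r in range(1, la + 1):
                cur[0] = np.inf
                ai = codes[i, r - 1]
                for c in range(1, lb + 1):
                    step = 0.0 if ai == codes[j, c - 1] else 1.0
                    m = prev[c - 1]
                    if prev[c] < m:
                        m = prev[c]
                    if cur[c - 1] < m:
                        m = cur[c - 1]
                    cur[c] = step + m
                for c in range(lb + 1):
                    prev[c] = cur[c]
            d = prev[lb] / np.sqrt(la * lb)
            out[i, j] = d
            out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# Combined distance and pairwise matrix
# ---------------------------------------------------------------------------

def default_sequence_weight(schema: FeatureSchema) -> float:
    """The sequence counts as one feature: weight 1 / (n_static + 1)."""
    return 1.0 / (len(schema.static_features) + 1)


def combined_distance(
    a: tuple[Mapping, Sequence[str]],
    b: tuple[Mapping, Sequence[str]],
    schema: FeatureSchema,
    ranges: Mapping[str, float],
    weight_seq: float | None = None,
) -> float:
    """weight_seq * dtw_gower + (1 - weight_seq) * gower_record."""
    if weight_seq is None:
        weight_seq = default_sequence_weight(schema)
    if not 0.0 <= weight_seq <= 1.0:
        raise ValueError(f"weight_seq must be in [0, 1], got {weight_seq}")
    static_a, seq_a = a
    static_b, seq_b = b
    return weight_seq * dtw_gower(seq_a, seq_b) + (1.0 - weight_seq) * gower_record(
        static_a, static_b, schema, ranges
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise combined distances over a pooled record set."""

    ids: list[str]
    origins: list[str]
    combined: np.ndarray
    static_part: np.ndarray
    seq_part: np.ndarray
    weight_seq: float

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("combined", "static_part", "seq_part"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if np.max(np.abs(m - m.T)) > 1e-12 or np.max(np.abs(np.diag(m))) > 0:
                raise ValueError(f"{name} must be symmetric with zero diagonal")
        if self.static_part.min() < 0 or self.static_part.max() > 1 + 1e-12:
            raise ValueError("static part entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.combined, index=self.ids, columns=self.ids).to_csv(path)


def pairwise_matrix(
    datasets: Sequence[LongitudinalDataset],
    schema: FeatureSchema | None = None,
    weight_seq: float | None = None,
) -> DistanceMatrix:
    """Combined pairwise distances over the pooled records of ``datasets``.

    Numeric Gower ranges are taken over the pool; origin tags are carried
    through in id order for downstream mixing diagnostics.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if schema is None:
        schema = datasets[0].schema
    ranges = pooled_ranges(datasets, schema)

    ids: list[str] = []
    origins: list[str] = []
    for d in datasets:
        ids.extend(d.patient_ids)
        origins.extend([d.origin_tag] * d.n_patients)
    n = len(ids)

    # static Gower, vectorized feature by feature
    static_sum = np.zeros((n, n))
    for f in schema.static_features:
        col = np.concatenate([d.static[f.name].to_numpy() for d in datasets])
        if f.kind == "numeric":
            v = col.astype(float)
            rng = ranges[f.name]
            part = np.abs(v[:, None] - v[None, :]) / rng if rng > 0 else np.zeros((n, n))
        else:
            part = (col[:, None] != col[None, :]).astype(float)
        static_sum += part
    static_part = static_sum / len(schema.static_features)

    # sequence DTW via the jitted kernel on integer-coded, padded sequences
    label_code = {lab: i for i, lab in enumerate(schema.chapter_labels)}
    seqs = [d.sequences[pid] for d in datasets for pid in d.patient_ids]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    tmax = int(lengths.max())
    codes = np.full((n, tmax), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = [label_code[c] for c in s]
    seq_part = _dtw_pairwise_int(codes, lengths)

    if weight_seq is None:
        weight_seq = default_sequence_weight(schema)
    if not 0.0 <= weight_seq <= 1.0:
        raise ValueError(f"weight_seq must be in [0, 1], got {weight_seq}")
    combined = weight_seq * seq_part + (1.0 - weight_seq) * static_part
    # exact symmetry for downstream validation
    combined = (combined + combined.T) / 2.0
    static_part = (static_part + static_part.T) / 2.0
    np.fill_diagonal(combined, 0.0)
    np.fill_diagonal(static_part, 0.0)
    return DistanceMatrix(
        ids=ids,
        origins=origins,
        combined=combined,
        static_part=static_part,
        seq_part=seq_part,
        weight_seq=weight_seq,
    )
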