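"""Train-Synthetic-Test-Real (TSTR) utility evaluation.

Two clinical tasks compare a model trained on real data against a model
trained on synthetic data, both scored on held-out real test folds:

* in-hospital mortality prediction (binary, rank-based AUC) from static
  attributes (excluding the target) and the chapter sequence, with folds
  stratified on the mortality label;
* next-step diagnosis prediction (14-class accuracy), where every
  patient contributes one instance per prefix of length >= 1 (prefix of
  chapters + static attributes -> next chapter) and folds are split by
  patient id, never by instance, so no patient leaks across splits.

The synthetic-trained model uses the full synthetic dataset; since that
training set does not vary with the fold and training is deterministic,
it is trained once and scored on every real test fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import FeatureSchema, LongitudinalDataset
from .models import (
    EncodedBatch,
    ModelSpec,
    StaticScaler,
    TrainConfig,
    binary_spec,
    encode_batch,
    fit,
    multiclass_spec,
    predict,
    train_val_split,
)

__all__ = ["TSTRResult", "mortality_tstr", "nextstep_tstr"]


@dataclass
class TSTRResult:
    """Paired real-trained vs synthetic-trained fold metrics for one task."""

    task: str  # "mortality" | "next_step"
    metric: str  # "auc" | "accuracy"
    fold_real: list[float]
    fold_synth: list[float]
    seed: int

    @property
    def real_mean(self) -> float:
        return float(np.mean(self.fold_real))

    @property
    def real_sd(self) -> float:
        return float(np.std(self.fold_real, ddof=1))

    @property
    def synth_mean(self) -> float:
        return float(np.mean(self.fold_synth))

    @property
    def synth_sd(self) -> float:
        return float(np.std(self.fold_synth, ddof=1))

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "metric": self.metric,
            "real_mean": self.real_mean,
            "real_sd": self.real_sd,
            "synth_mean": self.synth_mean,
            "synth_sd": self.synth_sd,
            "fold_real": [float(v) for v in self.fold_real],
            "fold_synth": [float(v) for v in self.fold_synth],
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

def _mortality_target(dataset: LongitudinalDataset) -> np.ndarray:
    return (dataset.static["deceased"].astype(str) == "yes").to_numpy(float)


def mortality_tstr(
    real: LongitudinalDataset,
    synthetic: LongitudinalDataset,
    spec: ModelSpec | None = None,
    k_folds: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    val_fraction: float = 0.1,
) -> TSTRResult:
    """In-hospital mortality AUC, real-trained vs synthetic-trained."""
    schema = real.schema
    if "deceased" not in schema.feature_names or "deceased" not in synthetic.schema.feature_names:
        raise ValueError("both datasets need the 'deceased' attribute")
    y_real = _mortality_target(real)
    if len(np.unique(y_real)) < 2:
        raise ValueError("real 'deceased' attribute has a single class")
    spec = spec if spec is not None else binary_spec(seed=seed)
    train_config = train_config if train_config is not None else TrainConfig(seed=seed)
    exclude = ("deceased",)
    pad_to = int(max(real.lengths().max(), synthetic.lengths().max()))

    # synthetic-trained model: full synthetic set, trained once
    y_syn = _mortality_target(synthetic)
    syn_scaler = StaticScaler.fit(synthetic, schema)
    syn_batch = encode_batch(
        synthetic, schema, syn_scaler, exclude_static=exclude,
        targets={"y": y_syn}, pad_to=pad_to,
    )
    strat = y_syn if len(np.unique(y_syn)) > 1 else None
    tr_s, va_s = train_val_split(syn_batch, val_fraction, seed=seed + 7919, stratify=strat)
    model_syn = fit(spec, tr_s, va_s, train_config)

    ids = np.asarray(real.patient_ids)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_real: list[float] = []
    fold_synth: list[float] = []
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(ids, y_real)):
        train_ds, test_ds = real.subset(ids[tr_idx]), real.subset(ids[te_idx])
        scaler = StaticScaler.fit(train_ds, schema)
        tr_batch = encode_batch(
            train_ds, schema, scaler, exclude_static=exclude,
            targets={"y": y_real[tr_idx]}, pad_to=pad_to,
        )
        tr, va = train_val_split(
            tr_batch, val_fraction, seed=seed * 1000 + fold_i, stratify=y_real[tr_idx]
        )
        model_real = fit(spec, tr, va, train_config)

        te_real = encode_batch(test_ds, schema, scaler, exclude_static=exclude, pad_to=pad_to)
        te_syn = encode_batch(test_ds, schema, syn_scaler, exclude_static=exclude, pad_to=pad_to)
        y_te = y_real[te_idx]
        fold_real.append(float(roc_auc_score(y_te, predict(model_real, te_real))))
        fold_synth.append(float(roc_auc_score(y_te, predict(model_syn, te_syn))))

    return TSTRResult("mortality", "auc", fold_real, fold_synth, seed)


# ---------------------------------------------------------------------------
# Next-step diagnosis
# ---------------------------------------------------------------------------

def _nextstep_instances(
    dataset: LongitudinalDataset,
    schema: FeatureSchema,
    scaler: StaticScaler,
    ids: np.ndarray,
    pad_to: int,
    exclude_static: tuple[str, ...] = (),
) -> EncodedBatch:
    """One instance per prefix: (static, chapters[:t]) -> chapters[t]."""
    sub = dataset.subset(ids)
    base = encode_batch(sub, schema, scaler, exclude_static=exclude_static)
    label_code = {lab: i for i, lab in enumerate(schema.chapter_labels)}

    rows_static, rows_seq, rows_len, rows_y, inst_ids = [], [], [], [], []
    for i, pid in enumerate(sub.patient_ids):
        seq = sub.sequences[pid]
        for t in range(1, len(seq)):
            rows_static.append(base.x_static[i])
            x = np.zeros((pad_to, len(schema.chapter_labels)))
            x[:t] = base.x_seq[i, :t]
            rows_seq.append(x)
            rows_len.append(t)
            rows_y.append(label_code[seq[t]])
            inst_ids.append(f"{pid}#{t}")
    if not rows_y:
        raise ValueError("no sequences of length >= 2: next-step task undefined")
    lengths = np.asarray(rows_len, dtype=np.int64)
    mask = np.zeros((len(rows_y), pad_to))
    for i, L in enumerate(lengths):
        mask[i, :L] = 1.0
    return EncodedBatch(
        x_static=np.asarray(rows_static),
        x_seq=np.asarray(rows_seq),
        lengths=lengths,
        mask=mask,
        static_names=base.static_names,
        targets={"y": np.asarray(rows_y, dtype=np.int64)},
        ids=inst_ids,
    )


def _accuracy(model, batch: EncodedBatch) -> float:
    probs = predict(model, batch)
    return float(np.mean(np.argmax(probs, axis=1) == batch.targets["y"]))


def nextstep_tstr(
    real: LongitudinalDataset,
    synthetic: LongitudinalDataset,
    spec: ModelSpec | None = None,
    k_folds: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    val_fraction: float = 0.1,
) -> TSTRResult:
    """Next-step diagnosis accuracy (14 classes), real- vs synthetic-trained."""
    schema = real.schema
    if int(real.lengths().max()) < 2 or int(synthetic.lengths().max()) < 2:
        raise ValueError("need sequences of length >= 2 for next-step prediction")
    k = len(schema.chapter_labels)
    spec = spec if spec is not None else multiclass_spec(k, seed=seed)
    train_config = train_config if train_config is not None else TrainConfig(seed=seed)
    # prefixes run to length L-1, so padding to max length - 1 suffices
    pad_to = int(max(real.lengths().max(), synthetic.lengths().max())) - 1

    syn_ids = np.asarray(synthetic.patient_ids)
    syn_scaler = StaticScaler.fit(synthetic, schema)
    rng = np.random.default_rng(seed + 104729)
    syn_perm = rng.permutation(syn_ids)
    n_val = max(1, int(round(val_fraction * len(syn_ids))))
    va_batch_s = _nextstep_instances(synthetic, schema, syn_scaler, syn_perm[:n_val], pad_to)
    tr_batch_s = _nextstep_instances(synthetic, schema, syn_scaler, syn_perm[n_val:], pad_to)
    model_syn = fit(spec, tr_batch_s, va_batch_s, train_config)

    ids = np.asarray(real.patient_ids)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_real: list[float] = []
    fold_synth: list[float] = []
    for fold_i, (tr_idx, te_idx) in enumerate(kf.split(ids)):
        scaler = StaticScaler.fit(real.subset(ids[tr_idx]), schema)
        rng_f = np.random.default_rng(seed * 1000 + fold_i)
        tr_ids = rng_f.permutation(ids[tr_idx])
        n_val_f = max(1, int(round(val_fraction * len(tr_ids))))
        va_b = _nextstep_instances(real, schema, scaler, tr_ids[:n_val_f], pad_to)
        tr_b = _nextstep_instances(real, schema, scaler, tr_ids[n_val_f:], pad_to)
        model_real = fit(spec, tr_b, va_b, train_config)

        te_real = _nextstep_instances(real, schema, scaler, ids[te_idx], pad_to)
        te_syn = _nextstep_instances(real, schema, syn_scaler, ids[te_idx], pad_to)
        fold_real.append(_accuracy(model_real, te_real))
        fold_synth.append(_accuracy(model_syn, te_syn))

    return TSTRResult("next_step", "accuracy", fold_real, fold_synth, seed)
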