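"""Classifier two-sample goodness-of-fit test for synthetic vs real cohorts.

Pooled real and synthetic records are labeled z = 1 for synthetic and a
recurrent discriminator is trained to approximate p(z | X).  Minimizing
its cross-entropy is equivalent to the variational approximation of the
posterior of the binary origin label, so held-out accuracy near 50%
indicates the two distributions are indistinguishable to the model class,
while the distribution of held-out predictions supports an explicit
two-sample Kolmogorov-Smirnov test of H0: the latent encodings of real
and synthetic data coincide.  Concentrated synthetic prediction mass is
the univariate signature of mode collapse.

Cross-validation is 10-fold by default, stratified on the origin label;
the KS statistic is computed per fold on that fold's held-out
predictions (pooling folds would correlate samples), and the headline
p-value is the median across folds with all folds reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data_model import LongitudinalDataset, concat_datasets
from .models import (
    ModelSpec,
    StaticScaler,
    TrainConfig,
    binary_spec,
    encode_batch,
    fit,
    predict,
    train_val_split,
)

__all__ = ["GoFResult", "gof_cv", "ks_two_sample", "prediction_density"]


@dataclass
class GoFResult:
    """Fold-wise discriminator accuracies, held-out predictions and KS tests."""

    fold_accuracies: list[float]
    fold_preds_real: list[np.ndarray]
    fold_preds_synth: list[np.ndarray]
    fold_ks: list[tuple[float, float]]  # (D, p) per fold
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def median_p(self) -> float:
        return float(np.median([p for _, p in self.fold_ks]))

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "fold_ks": [[float(d), float(p)] for d, p in self.fold_ks],
            "median_ks_p": self.median_p,
            "seed": self.seed,
        }


def ks_two_sample(preds_real, preds_synth) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF difference| and asymptotic p.

    Tests H0: the discriminator's latent encodings of real and synthetic
    records have the same distribution.
    """
    preds_real = np.asarray(preds_real, dtype=float)
    preds_synth = np.asarray(preds_synth, dtype=float)
    if preds_real.size == 0 or preds_synth.size == 0:
        raise ValueError("both prediction lists must be non-empty")
    res = stats.ks_2samp(preds_real, preds_synth, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def prediction_density(preds, grid_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of discriminator predictions with Scott's-rule bandwidth.

    Returns (grid, density) on a fixed grid over (0, 1).  Constant
    predictions have no spread to estimate a bandwidth from.
    """
    preds = np.asarray(preds, dtype=float)
    if preds.size < 2:
        raise ValueError("need at least 2 predictions for a density estimate")
    if np.ptp(preds) == 0:
        raise ValueError(
            "predictions are constant; a kernel density estimate is degenerate. "
            "Inspect the raw predictions directly (e.g. a rug plot) instead."
        )
    kde = stats.gaussian_kde(preds, bw_method="scott")
    grid = np.linspace(0.0, 1.0, grid_size)
    return grid, kde(grid)


def gof_cv(
    real: LongitudinalDataset,
    synthetic: LongitudinalDataset,
    spec: ModelSpec | None = None,
    k_folds: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    val_fraction: float = 0.1,
) -> GoFResult:
    """Cross-validated real-vs-synthetic discrimination with per-fold KS tests.

    Each fold trains the discriminator on the fold's training split (with
    an internal validation split for early stopping), records held-out
    accuracy at threshold 0.5 and the held-out predictions by true label,
    and runs the KS test on those predictions.
    """
    if real.n_patients == 0 or synthetic.n_patients == 0:
        raise ValueError("both datasets must be non-empty")
    if real.schema != synthetic.schema:
        raise ValueError("real and synthetic datasets must share a schema")
    n_total = real.n_patients + synthetic.n_patients
    if n_total < k_folds:
        raise ValueError(f"{n_total} records cannot fill {k_folds} folds")

    # pool under collision-free ids (the synthetic set may be a copy of real)
    r = real.copy(origin_tag="real")
    r.static.index = pd.Index([f"R_{i}" for i in r.static.index], name=r.static.index.name)
    r.sequences = {f"R_{i}": s for i, s in real.sequences.items()}
    s = synthetic.copy(origin_tag="synthetic")
    s.static.index = pd.Index([f"S_{i}" for i in s.static.index], name=s.static.index.name)
    s.sequences = {f"S_{i}": q for i, q in synthetic.sequences.items()}
    pool = concat_datasets(r, s)
    z = np.array([0] * r.n_patients + [1] * s.n_patients)
    ids = np.asarray(pool.patient_ids)

    spec = spec if spec is not None else binary_spec(seed=seed)
    train_config = train_config if train_config is not None else TrainConfig(seed=seed)
    schema = pool.schema
    pad_to = int(pool.lengths().max())

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    preds_r: list[np.ndarray] = []
    preds_s: list[np.ndarray] = []
    fold_ks: list[tuple[float, float]] = []
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(ids, z)):
        train_ds = pool.subset(ids[tr_idx])
        test_ds = pool.subset(ids[te_idx])
        scaler = StaticScaler.fit(train_ds, schema)
        tr_batch = encode_batch(
            train_ds, schema, scaler, targets={"y": z[tr_idx].astype(float)}, pad_to=pad_to
        )
        te_batch = encode_batch(
            test_ds, schema, scaler, targets={"y": z[te_idx].astype(float)}, pad_to=pad_to
        )
        tr, va = train_val_split(
            tr_batch, val_fraction, seed=seed * 1000 + fold_i, stratify=z[tr_idx]
        )
        model = fit(spec, tr, va, train_config)
        q = predict(model, te_batch)
        y_te = z[te_idx]
        fold_acc.append(float(np.mean((q >= 0.5).astype(int) == y_te)))
        qr, qs = q[y_te == 0], q[y_te == 1]
        preds_r.append(qr)
        preds_s.append(qs)
        fold_ks.append(ks_two_sample(qr, qs))

    return GoFResult(
        fold_accuracies=fold_acc,
        fold_preds_real=preds_r,
        fold_preds_synth=preds_s,
        fold_ks=fold_ks,
        seed=seed,
    )
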