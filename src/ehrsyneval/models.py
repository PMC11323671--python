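"""Recurrent discriminative backbone shared by the GoF, TSTR and AIA tasks.

Architecture: a dense (ReLU) branch for static inputs and a GRU branch
for the one-hot chapter sequence, joined by a fully-connected ReLU layer
feeding one or more output heads (binary sigmoid, multiclass softmax, or
scalar regression trained with absolute error).  Sequences are padded and
masked; the masked update leaves the hidden state untouched on padding
steps, so the recurrent summary is exactly the state after the last valid
step and appending padding never changes a prediction.

The network is implemented directly on NumPy arrays (float32, with the
recurrence compiled by numba) with manual backpropagation through time
and Adam updates, and is single-threaded-deterministic: identical
(spec, config, seed, data) give identical parameters and predictions.
Training uses early stopping on validation loss and restores the
best-validation state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .data_model import FeatureSchema, LongitudinalDataset

__all__ = [
    "Head",
    "ModelSpec",
    "TrainConfig",
    "StaticScaler",
    "EncodedBatch",
    "encode_batch",
    "fit",
    "predict",
    "train_val_split",
]

_EPS = 1e-7


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Head:
    """One output head: kind in {binary, multiclass, regression}."""

    name: str
    kind: str
    dim: int = 1
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("binary", "multiclass", "regression"):
            raise ValueError(f"unknown head kind {self.kind!r}")
        if self.kind == "multiclass" and self.dim < 2:
            raise ValueError("multiclass head needs dim >= 2")
        if self.kind in ("binary", "regression") and self.dim != 1:
            raise ValueError(f"{self.kind} head must have dim 1")


@dataclass(frozen=True)
class ModelSpec:
    """Backbone widths plus the output head(s)."""

    static_hidden: int = 16
    gru_hidden: int = 32
    joint_hidden: int = 32
    heads: tuple[Head, ...] = (Head("y", "binary"),)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.static_hidden, self.gru_hidden, self.joint_hidden) <= 0:
            raise ValueError("all widths must be positive")
        if len(self.heads) < 1:
            raise ValueError("need at least one output head")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def binary_spec(seed: int = 0, **kw) -> ModelSpec:
    return ModelSpec(heads=(Head("y", "binary"),), seed=seed, **kw)


def multiclass_spec(k: int, seed: int = 0, **kw) -> ModelSpec:
    return ModelSpec(heads=(Head("y", "multiclass", k),), seed=seed, **kw)


def regression_spec(seed: int = 0, **kw) -> ModelSpec:
    return ModelSpec(heads=(Head("y", "regression"),), seed=seed, **kw)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 3e-3
    patience: int = 8
    seed: int = 0
    #: evaluate the loss on the full training fold after each epoch (costs one
    #: extra forward pass; otherwise the running minibatch mean is recorded)
    track_train_loss: bool = False

    def __post_init__(self):
        if min(self.max_epochs, self.batch_size, self.patience) <= 0:
            raise ValueError("max_epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaticScaler:
    """Min-max statistics for numeric static features, fitted on training data."""

    mins: tuple[tuple[str, float], ...]
    maxs: tuple[tuple[str, float], ...]

    @classmethod
    def fit(cls, dataset: LongitudinalDataset, schema: FeatureSchema) -> "StaticScaler":
        mins, maxs = [], []
        for f in schema.static_features:
            if f.kind == "numeric":
                v = dataset.static[f.name].to_numpy(float)
                mins.append((f.name, float(v.min())))
                maxs.append((f.name, float(v.max())))
        return cls(mins=tuple(mins), maxs=tuple(maxs))

    def scale(self, name: str, values: np.ndarray) -> np.ndarray:
        lo = dict(self.mins)[name]
        hi = dict(self.maxs)[name]
        if hi == lo:
            return np.zeros_like(values, dtype=float)
        return (values - lo) / (hi - lo)


@dataclass
class EncodedBatch:
    """Model-ready arrays: scaled/one-hot statics, padded one-hot sequences, mask."""

    x_static: np.ndarray  # (n, d_static)
    x_seq: np.ndarray  # (n, T, C) one-hot, zero on padding
    lengths: np.ndarray  # (n,)
    mask: np.ndarray  # (n, T) 1.0 on valid steps
    static_names: list[str]  # input column names, for hygiene checks
    targets: dict[str, np.ndarray] = field(default_factory=dict)
    ids: list[str] | None = None

    def __post_init__(self):
        # single-precision throughout: the network trains in float32
        self.x_static = np.ascontiguousarray(self.x_static, dtype=np.float32)
        self.x_seq = np.ascontiguousarray(self.x_seq, dtype=np.float32)
        self.mask = np.ascontiguousarray(self.mask, dtype=np.float32)
        self.targets = {
            k: (v if np.issubdtype(v.dtype, np.integer) else v.astype(np.float32))
            for k, v in self.targets.items()
        }
        n = self.x_static.shape[0]
        if self.x_seq.shape[0] != n or self.mask.shape[:2] != self.x_seq.shape[:2]:
            raise ValueError("inconsistent batch array shapes")
        if not np.array_equal(self.mask.sum(axis=1).astype(int), self.lengths):
            raise ValueError("mask must mark exactly the valid steps")

    @property
    def n(self) -> int:
        return self.x_static.shape[0]

    def take(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(
            x_static=self.x_static[idx],
            x_seq=self.x_seq[idx],
            lengths=self.lengths[idx],
            mask=self.mask[idx],
            static_names=self.static_names,
            targets={k: v[idx] for k, v in self.targets.items()},
            ids=[self.ids[i] for i in idx] if self.ids is not None else None,
        )


def encode_batch(
    dataset: LongitudinalDataset,
    schema: FeatureSchema,
    scaler: StaticScaler,
    exclude_static: Sequence[str] = (),
    targets: Mapping[str, np.ndarray] | None = None,
    pad_to: int | None = None,
) -> EncodedBatch:
    """Encode a dataset: min-max numerics + one-hot categoricals + padded one-hot
    sequences with a validity mask.

    ``exclude_static`` drops features from the inputs (targets of a task,
    or sensitive attributes under attack).  ``scaler`` must have been
    fitted on training data only.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in schema.static_features:
        if f.name in exclude_static:
            continue
        if f.kind == "numeric":
            cols.append(scaler.scale(f.name, dataset.static[f.name].to_numpy(float)))
            names.append(f.name)
        else:
            vals = dataset.static[f.name].astype(str).to_numpy()
            unseen = set(vals) - set(f.domain)
            if unseen:
                raise ValueError(f"feature {f.name!r}: categories {sorted(unseen)} not in schema")
            for cat in f.domain:
                cols.append((vals == cat).astype(float))
                names.append(f"{f.name}={cat}")
    n = dataset.n_patients
    x_static = np.column_stack(cols) if cols else np.zeros((n, 0))

    label_code = {lab: i for i, lab in enumerate(schema.chapter_labels)}
    seqs = [dataset.sequences[pid] for pid in dataset.patient_ids]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    T = int(lengths.max()) if pad_to is None else int(pad_to)
    if T < lengths.max():
        raise ValueError("pad_to shorter than the longest sequence")
    C = len(schema.chapter_labels)
    x_seq = np.zeros((n, T, C))
    mask = np.zeros((n, T))
    for i, s in enumerate(seqs):
        codes = [label_code[c] for c in s]
        x_seq[i, np.arange(len(s)), codes] = 1.0
        mask[i, : len(s)] = 1.0
    return EncodedBatch(
        x_static=x_static,
        x_seq=x_seq,
        lengths=lengths,
        mask=mask,
        static_names=names,
        targets=dict(targets or {}),
        ids=list(dataset.patient_ids),
    )


def train_val_split(
    batch: EncodedBatch, val_fraction: float, seed: int, stratify: np.ndarray | None = None
) -> tuple[EncodedBatch, EncodedBatch]:
    """Random (optionally stratified) train/validation split of one batch."""
    n = batch.n
    n_val = max(1, int(round(val_fraction * n)))
    if n_val >= n:
        raise ValueError("validation fraction leaves no training data")
    rng = np.random.default_rng(seed)
    if stratify is not None:
        val_idx: list[int] = []
        for v in np.unique(stratify):
            members = np.flatnonzero(stratify == v)
            members = rng.permutation(members)
            k = max(1, int(round(val_fraction * len(members)))) if len(members) > 1 else 0
            val_idx.extend(members[:k])
        val = np.array(sorted(val_idx), dtype=int)
    else:
        val = np.sort(rng.permutation(n)[:n_val])
    train = np.setdiff1d(np.arange(n), val)
    return batch.take(train), batch.take(val)


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    lim = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@njit(cache=True, fastmath=True)
def _gru_forward(xp, Wh, bh, mask):  # pragma: no cover - exercised via _Network
    """Masked GRU over time.  xp: (n, T, 3H) precomputed input projections.

    Padding steps (mask 0) are identity updates, so they are skipped
    outright: the hidden state after the last valid step is exactly the
    recurrent summary, and appended padding can never change it.
    """
    n, T, H3 = xp.shape
    H = H3 // 3
    h = np.zeros((n, H), dtype=xp.dtype)
    hs_prev = np.empty((T, n, H), dtype=xp.dtype)
    rs = np.empty((T, n, H), dtype=xp.dtype)
    zs = np.empty((T, n, H), dtype=xp.dtype)
    ns = np.empty((T, n, H), dtype=xp.dtype)
    hns = np.empty((T, n, H), dtype=xp.dtype)
    for t in range(T):
        hh = np.dot(h, Wh)
        for i in range(n):
            if mask[i, t] == 0.0:
                continue
            for j in range(H):
                r = 1.0 / (1.0 + np.exp(-(xp[i, t, j] + hh[i, j] + bh[j])))
                z = 1.0 / (1.0 + np.exp(-(xp[i, t, H + j] + hh[i, H + j] + bh[H + j])))
                hn = hh[i, 2 * H + j] + bh[2 * H + j]
                nn = np.tanh(xp[i, t, 2 * H + j] + r * hn)
                hp = h[i, j]
                hs_prev[t, i, j] = hp
                rs[t, i, j] = r
                zs[t, i, j] = z
                ns[t, i, j] = nn
                hns[t, i, j] = hn
                h[i, j] = (1.0 - z) * nn + z * hp
    return h, hs_prev, rs, zs, ns, hns


@njit(cache=True, fastmath=True)
def _gru_backward(dh_last, Wh, mask, hs_prev, rs, zs, ns, hns):  # pragma: no cover
    """Backprop through time; returns d(input projections), dWh, dbh."""
    T, n, H = rs.shape
    WhT = np.ascontiguousarray(Wh.T)
    dWh = np.zeros_like(Wh)
    dbh = np.zeros(3 * H, dtype=Wh.dtype)
    dxp = np.zeros((n, T, 3 * H), dtype=Wh.dtype)
    dgh = np.empty((n, 3 * H), dtype=Wh.dtype)
    dh = dh_last.copy()
    for t in range(T - 1, -1, -1):
        any_valid = False
        for i in range(n):
            if mask[i, t] == 0.0:
                for j in range(3 * H):
                    dgh[i, j] = 0.0
                continue
            any_valid = True
            for j in range(H):
                r = rs[t, i, j]
                z = zs[t, i, j]
                nn = ns[t, i, j]
                hn = hns[t, i, j]
                hp = hs_prev[t, i, j]
                dh_new = dh[i, j]
                dz = dh_new * (hp - nn) * z * (1.0 - z)
                dnn = dh_new * (1.0 - z) * (1.0 - nn * nn)
                dr = dnn * hn * r * (1.0 - r)
                dxp[i, t, j] = dr
                dxp[i, t, H + j] = dz
                dxp[i, t, 2 * H + j] = dnn
                dgh[i, j] = dr
                dgh[i, H + j] = dz
                dgh[i, 2 * H + j] = dnn * r
                dh[i, j] = dh_new * z
        if not any_valid:
            continue
        dWh += np.dot(_masked_rows_T(hs_prev[t], mask[:, t]), dgh)
        for c in range(3 * H):
            s = 0.0
            for i in range(n):
                s += dgh[i, c]
            dbh[c] += s
        dh += np.dot(dgh, WhT)
    return dxp, dWh, dbh


@njit(cache=True)
def _masked_rows_T(a, m):  # pragma: no cover
    """Transpose of ``a`` with masked-out rows zeroed (their cache is undefined)."""
    n, H = a.shape
    out = np.zeros((H, n), dtype=a.dtype)
    for i in range(n):
        if m[i] != 0.0:
            for j in range(H):
                out[j, i] = a[i, j]
    return out


class _Network:
    """Parameter container + forward/backward for the two-branch GRU net."""

    def __init__(self, spec: ModelSpec, d_static: int, d_seq: int):
        self.spec = spec
        self.d_static = d_static
        self.d_seq = d_seq
        rng = np.random.default_rng(spec.seed)
        H, DS, DJ = spec.gru_hidden, spec.static_hidden, spec.joint_hidden
        self.use_static = d_static > 0
        p: dict[str, np.ndarray] = {}
        if self.use_static:
            p["Ws"] = _glorot(rng, (d_static, DS))
            p["bs"] = np.zeros(DS, dtype=np.float32)
        p["Wx"] = _glorot(rng, (d_seq, 3 * H))
        p["Wh"] = _glorot(rng, (H, 3 * H))
        p["bx"] = np.zeros(3 * H, dtype=np.float32)
        p["bh"] = np.zeros(3 * H, dtype=np.float32)
        d_joint_in = (DS if self.use_static else 0) + H
        p["Wj"] = _glorot(rng, (d_joint_in, DJ))
        p["bj"] = np.zeros(DJ, dtype=np.float32)
        for h in spec.heads:
            p[f"Wo_{h.name}"] = _glorot(rng, (DJ, h.dim))
            p[f"bo_{h.name}"] = np.zeros(h.dim, dtype=np.float32)
        self.params = p

    # -- forward ----------------------------------------------------------
    def forward(self, batch: EncodedBatch, drop_rng: np.random.Generator | None = None):
        p = self.params
        H = self.spec.gru_hidden
        n = batch.n
        T = int(batch.lengths.max()) if n else 0
        xs = batch.x_seq[:, :T, :]
        mask = batch.mask[:, :T]

        cache: dict = {"T": T}
        if self.use_static:
            s_pre = batch.x_static @ p["Ws"] + p["bs"]
            s = np.maximum(s_pre, 0.0)
            cache["s"] = s
        # precompute input projections for every step in one GEMM,
        # then run the masked recurrence in the compiled kernel
        xp = xs.reshape(n * T, self.d_seq) @ p["Wx"] + p["bx"]
        xp = np.ascontiguousarray(xp.reshape(n, T, 3 * H))
        h, hs_prev, rs, zs, ns, hns = _gru_forward(
            xp, p["Wh"], p["bh"], np.ascontiguousarray(mask)
        )
        cache.update(hs_prev=hs_prev, rs=rs, zs=zs, ns=ns, hns=hns, h_last=h, mask=mask)

        j_in = np.concatenate([cache["s"], h], axis=1) if self.use_static else h
        j_pre = j_in @ p["Wj"] + p["bj"]
        j = np.maximum(j_pre, 0.0)
        if drop_rng is not None and self.spec.dropout > 0.0:
            keep = 1.0 - self.spec.dropout
            dmask = (drop_rng.random(j.shape) < keep) / keep
            j = j * dmask
            cache["dmask"] = dmask
        cache.update(j_in=j_in, j=j)

        outputs: dict[str, np.ndarray] = {}
        for hd in self.spec.heads:
            o = j @ p[f"Wo_{hd.name}"] + p[f"bo_{hd.name}"]
            if hd.kind == "binary":
                outputs[hd.name] = np.clip(_sigmoid(o[:, 0]), _EPS, 1.0 - _EPS)
            elif hd.kind == "multiclass":
                outputs[hd.name] = _softmax(o)
            else:
                outputs[hd.name] = o[:, 0]
        return outputs, cache

    # -- loss -------------------------------------------------------------
    def loss(self, outputs: dict[str, np.ndarray], targets: dict[str, np.ndarray]) -> float:
        total = 0.0
        for hd in self.spec.heads:
            q = outputs[hd.name]
            y = targets[hd.name]
            if hd.kind == "binary":
                l = -np.mean(y * np.log(q) + (1.0 - y) * np.log(1.0 - q))
            elif hd.kind == "multiclass":
                l = -np.mean(np.log(np.clip(q[np.arange(len(y)), y.astype(int)], _EPS, None)))
            else:
                l = np.mean(np.abs(q - y))
            total += hd.weight * l
        return float(total)

    # -- backward ---------------------------------------------------------
    def grads(self, batch: EncodedBatch, outputs, cache) -> dict[str, np.ndarray]:
        p = self.params
        H = self.spec.gru_hidden
        n = batch.n
        T = cache["T"]
        g = {k: np.zeros_like(v) for k, v in p.items()}

        dj = np.zeros_like(cache["j"])
        for hd in self.spec.heads:
            q = outputs[hd.name]
            y = batch.targets[hd.name]
            if hd.kind == "binary":
                do = ((q - y) / n)[:, None]
            elif hd.kind == "multiclass":
                do = q.copy()
                do[np.arange(n), y.astype(int)] -= 1.0
                do /= n
            else:
                do = (np.sign(q - y) / n)[:, None]
            do = hd.weight * do
            g[f"Wo_{hd.name}"] = cache["j"].T @ do
            g[f"bo_{hd.name}"] = do.sum(axis=0)
            dj += do @ p[f"Wo_{hd.name}"].T
        if "dmask" in cache:
            dj = dj * cache["dmask"]
        dj_pre = dj * (cache["j"] > 0)
        g["Wj"] = cache["j_in"].T @ dj_pre
        g["bj"] = dj_pre.sum(axis=0)
        dj_in = dj_pre @ p["Wj"].T

        if self.use_static:
            DS = self.spec.static_hidden
            ds = dj_in[:, :DS]
            dh = dj_in[:, DS:]
            ds_pre = ds * (cache["s"] > 0)
            g["Ws"] = batch.x_static.T @ ds_pre
            g["bs"] = ds_pre.sum(axis=0)
        else:
            dh = dj_in

        dxp, dWh, dbh = _gru_backward(
            np.ascontiguousarray(dh),
            p["Wh"],
            np.ascontiguousarray(cache["mask"]),
            cache["hs_prev"],
            cache["rs"],
            cache["zs"],
            cache["ns"],
            cache["hns"],
        )
        g["Wh"] = dWh
        g["bh"] = dbh
        xs = batch.x_seq[:, :T, :]
        g["Wx"] = xs.reshape(n * T, self.d_seq).T @ dxp.reshape(n * T, 3 * H)
        g["bx"] = dxp.sum(axis=(0, 1))
        return g


@dataclass
class TrainedModel:
    """Handle returned by :func:`fit`: parameters + encoding contract + history."""

    spec: ModelSpec
    net: _Network
    static_names: list[str]
    train_loss_history: list[float]
    val_loss_history: list[float]
    best_epoch: int
    best_val_loss: float


def fit(
    spec: ModelSpec,
    train: EncodedBatch,
    val: EncodedBatch,
    config: TrainConfig,
) -> TrainedModel:
    """Train with Adam + early stopping; restores the best-validation state."""
    if train.n == 0 or val.n == 0:
        raise ValueError("train and validation batches must be non-empty")
    if train.ids is not None and val.ids is not None:
        if set(train.ids) & set(val.ids):
            raise ValueError("train and validation sets share patient ids")
    for hd in spec.heads:
        if hd.name not in train.targets or hd.name not in val.targets:
            raise ValueError(f"batches lack target for head {hd.name!r}")

    net = _Network(spec, d_static=train.x_static.shape[1], d_seq=train.x_seq.shape[2])
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1) if spec.dropout > 0 else None

    m_state = {k: np.zeros_like(v) for k, v in net.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_params = copy.deepcopy(net.params)
    best_val = np.inf
    best_epoch = -1
    bad_epochs = 0
    train_hist: list[float] = []
    val_hist: list[float] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(train.n)
        mb_losses = []
        for start in range(0, train.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            mb = train.take(idx)
            outputs, cache = net.forward(mb, drop_rng=drop_rng)
            mb_losses.append(net.loss(outputs, mb.targets))
            grads = net.grads(mb, outputs, cache)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in net.params:
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                net.params[k] -= lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)

        if config.track_train_loss:
            tr_out, _ = net.forward(train)
            train_hist.append(net.loss(tr_out, train.targets))
        else:
            train_hist.append(float(np.mean(mb_losses)))
        va_out, _ = net.forward(val)
        val_loss = net.loss(va_out, val.targets)
        val_hist.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_epoch = epoch
            best_params = copy.deepcopy(net.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    net.params = best_params
    return TrainedModel(
        spec=spec,
        net=net,
        static_names=list(train.static_names),
        train_loss_history=train_hist,
        val_loss_history=val_hist,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
    )


def predict(model: TrainedModel, batch: EncodedBatch) -> np.ndarray | dict[str, np.ndarray]:
    """Per-record outputs: probability in (0,1), class-probability rows, or scalar.

    Returns the single head's array, or a dict of arrays for multi-head
    models.  The batch must have been encoded with the same static layout
    the model was trained on.
    """
    if list(batch.static_names) != model.static_names:
        raise ValueError(
            f"batch static layout {batch.static_names} does not match "
            f"the model's {model.static_names}"
        )
    outputs, _ = model.net.forward(batch)
    if len(model.spec.heads) == 1:
        return outputs[model.spec.heads[0].name]
    return outputs
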