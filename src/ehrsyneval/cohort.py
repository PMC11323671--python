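"""Simulator for MIMIC-like longitudinal cohorts with known ground truth.

The generator mirrors the two-step structure of attribute-conditional
sequence generators: static attributes are drawn first (truncated-normal
age, categorical gender/race with an explicit "unknown" mass, in-hospital
mortality through a logistic link on standardized age), then each patient
is assigned a stratum from its attributes and a diagnosis-chapter sequence
is drawn as a first-order Markov chain from that stratum's transition
matrix, with length supported on [5, 37].

Two injectors create known failure modes for the evaluation metrics:
``inject_mode_collapse`` (resample everything from k prototypes) and
``perturb_config`` (mix transition matrices toward a permuted reference by
a controllable weight), plus ``split_holdout`` for iid null designs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CHAPTER_LABELS,
    UNKNOWN,
    FeatureSchema,
    LongitudinalDataset,
    default_schema,
)

MIN_LEN, MAX_LEN = 5, 37
_SIMPLEX_TOL = 1e-9


def named_rng(seed: int, *names: str) -> np.random.Generator:
    """Derive an independent, reproducible stream from a root seed and names.

    All randomness in the package flows from one integer seed through
    these named streams, so each stage can be re-run or tested in
    isolation without consuming another stage's draws.
    """
    key = tuple(
        int.from_bytes(hashlib.sha256(n.encode()).digest()[:4], "little") for n in names
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


@dataclass(frozen=True, eq=False)
class CohortConfig:
    """Full specification of a simulated cohort."""

    n_patients: int = 1000
    age_mean: float = 71.0
    age_sd: float = 11.0
    age_min: float = 18.0
    age_max: float = 100.0
    #: (category, probability) over gender; must sum to 1
    gender_probs: tuple[tuple[str, float], ...] = (("M", 0.55), ("F", 0.45))
    #: race includes the "unknown" missing-category with its own mass
    race_probs: tuple[tuple[str, float], ...] = (
        ("white", 0.66),
        ("black", 0.10),
        ("hispanic", 0.05),
        ("asian", 0.04),
        ("other", 0.04),
        (UNKNOWN, 0.11),
    )
    #: logistic link for in-hospital mortality on standardized age:
    #: P(deceased) = sigmoid(intercept + slope * (age - age_mean)/age_sd)
    mortality_intercept: float = -2.197  # logit(0.10)
    mortality_slope: float = 0.8
    n_strata: int = 4
    #: per-stratum (n_strata, 14, 14) row-stochastic chapter transition matrices
    transition_matrices: np.ndarray = None  # type: ignore[assignment]
    #: per-stratum (n_strata, 14) first-step chapter distributions
    initial_distribution: np.ndarray = None  # type: ignore[assignment]
    #: probabilities over integer lengths MIN_LEN..MAX_LEN
    length_distribution: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.transition_matrices is None:
            object.__setattr__(
                self, "transition_matrices", _default_transitions(self.n_strata)
            )
        if self.initial_distribution is None:
            object.__setattr__(
                self, "initial_distribution", _default_initial(self.n_strata)
            )
        if self.length_distribution is None:
            object.__setattr__(self, "length_distribution", _default_lengths())
        self.validate()

    def validate(self) -> None:
        for name, probs in (("gender", self.gender_probs), ("race", self.race_probs)):
            total = sum(p for _, p in probs)
            if abs(total - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for _, p in probs):
                raise ValueError(f"{name} probabilities must be non-negative")
        T = np.asarray(self.transition_matrices, dtype=float)
        if T.shape != (self.n_strata, 14, 14):
            raise ValueError(f"transition matrices must be ({self.n_strata}, 14, 14)")
        if np.any(T < 0) or np.max(np.abs(T.sum(axis=2) - 1.0)) > _SIMPLEX_TOL:
            raise ValueError("transition matrix rows must be simplex vectors")
        P0 = np.asarray(self.initial_distribution, dtype=float)
        if P0.shape != (self.n_strata, 14):
            raise ValueError(f"initial distribution must be ({self.n_strata}, 14)")
        if np.any(P0 < 0) or np.max(np.abs(P0.sum(axis=1) - 1.0)) > _SIMPLEX_TOL:
            raise ValueError("initial distributions must be simplex vectors")
        L = np.asarray(self.length_distribution, dtype=float)
        if L.shape != (MAX_LEN - MIN_LEN + 1,):
            raise ValueError("length distribution must cover integers 5..37")
        if np.any(L < 0) or abs(L.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("length distribution must be a simplex vector")

    def schema(self) -> FeatureSchema:
        return default_schema()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortConfig):
            return NotImplemented
        for f in ("n_patients", "age_mean", "age_sd", "age_min", "age_max",
                  "gender_probs", "race_probs", "mortality_intercept",
                  "mortality_slope", "n_strata", "seed"):
            if getattr(self, f) != getattr(other, f):
                return False
        return (
            np.array_equal(self.transition_matrices, other.transition_matrices)
            and np.array_equal(self.initial_distribution, other.initial_distribution)
            and np.array_equal(self.length_distribution, other.length_distribution)
        )


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    return m / m.sum(axis=-1, keepdims=True)


def _default_transitions(n_strata: int) -> np.ndarray:
    """Structured, stratum-specific transition matrices (fixed recipe).

    Each stratum mixes a self-transition diagonal, a pull toward the
    circulatory chapter (the dominant diagnosis in an ischaemic-heart
    cohort), and a stratum-specific random component drawn from a fixed
    internal seed, so strata are reproducibly distinct.
    """
    rng = np.random.default_rng(20140814)
    circ = CHAPTER_LABELS.index("circulatory")
    mats = []
    for s in range(n_strata):
        base = rng.dirichlet(np.full(14, 0.6), size=14)
        m = 0.30 * np.eye(14) + 0.25 * np.eye(14)[circ][None, :] + 0.45 * base
        mats.append(_normalize_rows(m))
    return np.array(mats)


def _default_initial(n_strata: int) -> np.ndarray:
    rng = np.random.default_rng(19990221)
    circ = CHAPTER_LABELS.index("circulatory")
    rows = []
    for s in range(n_strata):
        v = rng.dirichlet(np.full(14, 1.0))
        v = 0.6 * v + 0.4 * np.eye(14)[circ]
        rows.append(v / v.sum())
    return np.array(rows)


def _default_lengths(mean: float = 15.0, sd: float = 7.0) -> np.ndarray:
    """Discretized truncated normal over [5, 37]."""
    grid = np.arange(MIN_LEN, MAX_LEN + 1)
    pdf = stats.norm.pdf(grid, loc=mean, scale=sd)
    return pdf / pdf.sum()


def default_config(n_patients: int = 1000, **overrides) -> CohortConfig:
    return CohortConfig(n_patients=n_patients, **overrides)


def assign_strata(gender: np.ndarray, age: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Stratum index per patient: gender x (age above/below its mean)."""
    g = (np.asarray(gender) == "F").astype(int)
    a = (np.asarray(age) > config.age_mean).astype(int)
    return (2 * g + a) % config.n_strata


def generate_cohort(
    config: CohortConfig, seed: int | None = None, origin_tag: str = "real"
) -> LongitudinalDataset:
    """Draw a full cohort; identical (config, seed) gives identical data."""
    seed = config.seed if seed is None else seed
    n = config.n_patients
    schema = config.schema()

    rng_age = named_rng(seed, "static", "age")
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng_age
    )
    age = np.round(age, 1)

    rng_gender = named_rng(seed, "static", "gender")
    g_cats, g_p = zip(*config.gender_probs)
    gender = rng_gender.choice(g_cats, size=n, p=np.asarray(g_p) / np.sum(g_p))

    rng_race = named_rng(seed, "static", "race")
    r_cats, r_p = zip(*config.race_probs)
    race = rng_race.choice(r_cats, size=n, p=np.asarray(r_p) / np.sum(r_p))

    rng_mort = named_rng(seed, "static", "mortality")
    z = (age - config.age_mean) / config.age_sd
    p_dec = 1.0 / (1.0 + np.exp(-(config.mortality_intercept + config.mortality_slope * z)))
    deceased = np.where(rng_mort.random(n) < p_dec, "yes", "no")

    strata = assign_strata(gender, age, config)

    rng_len = named_rng(seed, "seq", "length")
    lengths = rng_len.choice(
        np.arange(MIN_LEN, MAX_LEN + 1), size=n, p=config.length_distribution
    )

    rng_seq = named_rng(seed, "seq", "chain")
    T = np.asarray(config.transition_matrices, dtype=float)
    P0 = np.asarray(config.initial_distribution, dtype=float)
    # cumulative rows let the whole chain run on one uniform draw per step
    T_cum = np.cumsum(T, axis=2)
    P0_cum = np.cumsum(P0, axis=1)
    labels = list(CHAPTER_LABELS)

    sequences: dict[str, list[str]] = {}
    ids = [f"p{i:06d}" for i in range(n)]
    u_all = rng_seq.random((n, MAX_LEN))
    for i in range(n):
        s = strata[i]
        L = int(lengths[i])
        u = u_all[i]
        state = int(np.searchsorted(P0_cum[s], u[0], side="right"))
        seq = [labels[state]]
        for t in range(1, L):
            state = int(np.searchsorted(T_cum[s, state], u[t], side="right"))
            seq.append(labels[state])
        sequences[ids[i]] = seq

    static = pd.DataFrame(
        {"age": age, "gender": gender, "race": race, "deceased": deceased},
        index=pd.Index(ids, name=schema.id_field),
    )
    return LongitudinalDataset(
        schema=schema, static=static, sequences=sequences, origin_tag=origin_tag
    )


def inject_mode_collapse(
    dataset: LongitudinalDataset, k: int, seed: int
) -> LongitudinalDataset:
    """Resample the whole cohort (with replacement) from k prototype records.

    Emulates a collapsed generator: every output record duplicates one of at
    most k realistic patterns, so size and marginal realism are preserved
    while variety is destroyed.
    """
    n = dataset.n_patients
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = named_rng(seed, "mode_collapse")
    ids = np.asarray(dataset.patient_ids)
    prototypes = rng.choice(ids, size=k, replace=False)
    picks = rng.choice(prototypes, size=n, replace=True)
    new_ids = [f"mc{i:06d}" for i in range(n)]
    static = dataset.static.loc[picks].copy()
    static.index = pd.Index(new_ids, name=dataset.schema.id_field)
    sequences = {nid: list(dataset.sequences[src]) for nid, src in zip(new_ids, picks)}
    return LongitudinalDataset(
        schema=dataset.schema,
        static=static,
        sequences=sequences,
        origin_tag=dataset.origin_tag,
    )


def perturb_config(config: CohortConfig, shift: float) -> CohortConfig:
    """Mix every transition matrix toward a permuted reference by ``shift``.

    The reference permutes each matrix's columns cyclically, so shift=1
    redirects every transition's mass to the next chapter label while
    keeping rows stochastic; shift=0 returns an equal config.
    """
    if not 0.0 <= shift <= 1.0:
        raise ValueError(f"shift must be in [0, 1], got {shift}")
    if shift == 0.0:
        return replace(config)
    T = np.asarray(config.transition_matrices, dtype=float)
    permuted = np.roll(T, shift=1, axis=2)
    mixed = _normalize_rows((1.0 - shift) * T + shift * permuted)
    return replace(config, transition_matrices=mixed)


def split_holdout(
    dataset: LongitudinalDataset, fraction: float, seed: int
) -> tuple[LongitudinalDataset, LongitudinalDataset]:
    """Disjoint random partition with |part A| = round(fraction * n)."""
    n = dataset.n_patients
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_a = int(round(fraction * n))
    if n_a < 1 or n_a > n - 1:
        raise ValueError(f"fraction {fraction} produces an empty part at n={n}")
    rng = named_rng(seed, "holdout_split")
    perm = rng.permutation(np.asarray(dataset.patient_ids))
    return dataset.subset(perm[:n_a]), dataset.subset(perm[n_a:])
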