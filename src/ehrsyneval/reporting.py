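"""Descriptive statistics and end-to-end report assembly.

``run_report`` ties every evaluation stage into one reproducible run
driven by a YAML/JSON config: it loads or generates the real and
synthetic cohorts, executes the selected evaluations in a fixed order
(descriptives, projections, gof, utility, privacy), and writes a JSON
report plus figures and CSVs under one run directory.  All randomness
flows from the single config seed through named streams, and the JSON
report contains only values reproducible from (config, seed), so reruns
are numerically identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aia import aia_attack
from .cohort import (
    CohortConfig,
    generate_cohort,
    inject_mode_collapse,
    perturb_config,
    split_holdout,
)
from .data_model import LongitudinalDataset, default_schema, load_dataset
from .distances import pairwise_matrix
from .gof import gof_cv, prediction_density
from .models import ModelSpec, TrainConfig
from .projection import mixing_score, plot_projection, sweep
from .tstr import mortality_tstr, nextstep_tstr

__all__ = [
    "EvaluationReport",
    "descriptive_static",
    "stepwise_chapter_frequencies",
    "run_report",
]

logger = logging.getLogger("ehrsyneval")

_STAGES = ("descriptives", "projections", "gof", "utility", "privacy")


def _tool_version() -> str:
    try:
        return _pkg_version("ehrsyneval")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# Descriptive fidelity statistics
# ---------------------------------------------------------------------------

def descriptive_static(dataset: LongitudinalDataset) -> dict:
    """Per-feature summaries: five-number summary for numerics (age also on
    the /100 plotting scale), relative frequencies for categoricals."""
    out: dict = {}
    for f in dataset.schema.static_features:
        if f.kind == "numeric":
            v = dataset.static[f.name].to_numpy(float)
            summary = {
                "min": float(np.min(v)),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q3": float(np.percentile(v, 75)),
                "max": float(np.max(v)),
            }
            entry = {"kind": "numeric", "summary": summary}
            if f.name == "age":
                entry["plot_scale"] = {k: val / 100.0 for k, val in summary.items()}
            out[f.name] = entry
        else:
            freq = dataset.static[f.name].astype(str).value_counts(normalize=True)
            out[f.name] = {
                "kind": "categorical",
                "frequencies": {str(k): float(p) for k, p in freq.items()},
            }
    return out


def stepwise_chapter_frequencies(
    dataset: LongitudinalDataset, max_step: int = 37
) -> pd.DataFrame:
    """Step x chapter frequency matrix: entry (t, c) is the fraction of
    patients surviving to step t whose step-t chapter is c."""
    labels = list(dataset.schema.chapter_labels)
    counts = np.zeros((max_step, len(labels)))
    survivors = np.zeros(max_step)
    code = {lab: i for i, lab in enumerate(labels)}
    for seq in dataset.sequences.values():
        for t, chap in enumerate(seq[:max_step]):
            counts[t, code[chap]] += 1
            survivors[t] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(survivors[:, None] > 0, counts / survivors[:, None], 0.0)
    return pd.DataFrame(freq, index=pd.RangeIndex(1, max_step + 1, name="step"), columns=labels)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    config: dict
    sections: dict = field(default_factory=dict)
    tool_version: str = field(default_factory=_tool_version)

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config": self.config,
            "sections": self.sections,
        }


def _cohort_config_from(section: dict) -> CohortConfig:
    known = {
        "n_patients", "age_mean", "age_sd", "age_min", "age_max",
        "mortality_intercept", "mortality_slope", "n_strata", "seed",
    }
    kwargs = {k: v for k, v in section.items() if k in known}
    if "gender_probs" in section:
        kwargs["gender_probs"] = tuple((str(c), float(p)) for c, p in section["gender_probs"])
    if "race_probs" in section:
        kwargs["race_probs"] = tuple((str(c), float(p)) for c, p in section["race_probs"])
    return CohortConfig(**kwargs)


def _validate_config(cfg: dict) -> None:
    for key in ("out_dir", "seed", "real", "synthetic"):
        if key not in cfg:
            raise ValueError(f"config lacks required key {key!r}")
    for stage in cfg.get("evaluations", list(_STAGES)):
        if stage not in _STAGES:
            raise ValueError(f"unknown evaluation stage {stage!r}")
    for side in ("real", "synthetic"):
        sec = cfg[side]
        if not isinstance(sec, dict) or not (
            {"static", "sequences"} <= set(sec) or "generate" in sec or "derive" in sec
        ):
            raise ValueError(
                f"config section {side!r} must name static+sequences paths, "
                "a 'generate' recipe, or a 'derive' rule"
            )
    if "derive" in cfg["real"]:
        raise ValueError("the real cohort cannot be derived from itself")
    for side in ("real", "synthetic"):
        sec = cfg[side]
        if "static" in sec:
            for k in ("static", "sequences"):
                if not Path(sec[k]).exists():
                    raise ValueError(f"{side} {k} path {sec[k]!r} does not exist")


def _load_side(cfg: dict, side: str, seed: int, real: LongitudinalDataset | None):
    sec = cfg[side]
    tag = side
    if "static" in sec:
        ds = load_dataset(sec["static"], sec["sequences"], default_schema(), origin_tag=tag)
        return ds, None
    if "generate" in sec:
        gen = dict(sec["generate"])
        shift = float(gen.pop("shift", 0.0))
        config = _cohort_config_from(gen)
        if shift:
            config = perturb_config(config, shift)
        stream = 0 if side == "real" else 1
        return generate_cohort(config, seed=seed * 2 + stream, origin_tag=tag), None
    # derive: from the already-loaded real cohort
    rule = sec["derive"]
    if rule == "holdout":
        a, b = split_holdout(real, float(sec.get("fraction", 0.5)), seed=seed)
        return b.copy(origin_tag=tag), a
    if rule == "mode_collapse":
        return inject_mode_collapse(real, int(sec.get("k", 3)), seed=seed).copy(origin_tag=tag), None
    raise ValueError(f"unknown derive rule {rule!r}")


def run_report(config) -> tuple[EvaluationReport, Path]:
    """Execute the configured evaluations; returns the report and run directory."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    _validate_config(cfg)

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        seed = int(cfg["seed"])
        stages = list(cfg.get("evaluations", list(_STAGES)))
        k_folds = int(cfg.get("k_folds", 10))
        logger.info("run starting: seed=%s stages=%s k_folds=%s", seed, stages, k_folds)

        real, _ = _load_side(cfg, "real", seed, None)
        synthetic, maybe_real = _load_side(cfg, "synthetic", seed, real)
        if maybe_real is not None:
            real = maybe_real.copy(origin_tag="real")
        logger.info("cohorts: real n=%d, synthetic n=%d", real.n_patients, synthetic.n_patients)

        model_spec = ModelSpec(**cfg.get("model", {}), seed=seed) if cfg.get("model") else None
        train_cfg = TrainConfig(**{**cfg.get("train", {}), "seed": seed})

        report = EvaluationReport(config=cfg)
        for stage in _STAGES:
            if stage not in stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                if stage == "descriptives":
                    report.sections["descriptives"] = {
                        "real": descriptive_static(real),
                        "synthetic": descriptive_static(synthetic),
                    }
                    for name, ds in (("real", real), ("synthetic", synthetic)):
                        stepwise_chapter_frequencies(ds).to_csv(
                            out_dir / f"chapter_frequencies_{name}.csv"
                        )
                elif stage == "projections":
                    proj_cfg = cfg.get("projection", {})
                    dmat = pairwise_matrix([real, synthetic])
                    if proj_cfg.get("save_distance_matrix", False):
                        dmat.to_csv(out_dir / "distance_matrix.csv")
                    results = sweep(
                        dmat,
                        methods=proj_cfg.get("methods", ["tsne", "umap"]),
                        neighbor_values=proj_cfg.get("neighbor_values", [15, 25, 50]),
                        seed=seed,
                    )
                    k = int(proj_cfg.get("mixing_k", 10))
                    section = []
                    for res in results:
                        fname = f"projection_{res.method}_{res.n_neighbors}.png"
                        plot_projection(res, out_dir / fname)
                        section.append(
                            {
                                "method": res.method,
                                "n_neighbors": res.n_neighbors,
                                "mixing_score": mixing_score(res, k=k),
                                "figure": fname,
                            }
                        )
                    report.sections["projections"] = section
                elif stage == "gof":
                    res = gof_cv(
                        real, synthetic, spec=model_spec, k_folds=k_folds,
                        seed=seed, train_config=train_cfg,
                    )
                    report.sections["gof"] = res.to_dict()
                    preds = np.concatenate([res.fold_preds_real[0], res.fold_preds_synth[0]])
                    try:
                        grid, dens = prediction_density(preds)
                        pd.DataFrame({"prediction": grid, "density": dens}).to_csv(
                            out_dir / "gof_prediction_density.csv", index=False
                        )
                        _plot_density(res, out_dir / "gof_prediction_density.png")
                    except ValueError as exc:
                        logger.warning("density skipped: %s", exc)
                elif stage == "utility":
                    mort = mortality_tstr(
                        real, synthetic, spec=model_spec, k_folds=k_folds,
                        seed=seed, train_config=train_cfg,
                    )
                    nxt = nextstep_tstr(
                        real, synthetic, k_folds=k_folds, seed=seed, train_config=train_cfg,
                    )
                    report.sections["utility"] = {
                        "mortality": mort.to_dict(),
                        "next_step": nxt.to_dict(),
                    }
                elif stage == "privacy":
                    res = aia_attack(
                        synthetic, real, spec=model_spec, k_folds=k_folds,
                        seed=seed, train_config=train_cfg,
                    )
                    report.sections["privacy"] = res.to_dict()
                    res.to_dataframe().to_csv(out_dir / "aia_table.csv", index=False)
            except Exception as exc:
                raise RuntimeError(f"evaluation stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s done", stage)

        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        logger.info("report written to %s", out_dir / "report.json")
        return report, out_dir
    finally:
        logger.removeHandler(handler)
        handler.close()


def _plot_density(res, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for preds, label in (
        (res.fold_preds_real[0], "real"),
        (res.fold_preds_synth[0], "synthetic"),
    ):
        try:
            grid, dens = prediction_density(preds)
            ax.plot(grid, dens, label=label)
        except ValueError:
            continue
    ax.set_xlabel("discriminator prediction")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
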