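"""2-D projection of pooled real+synthetic distances with tSNE / UMAP.

Both algorithms run in precomputed-distance mode on the combined
DTW+Gower matrix, with random initialization under a fixed seed (data-
space initialization is unavailable when only distances are given).  The
neighbor-count hyperparameter - perplexity in tSNE, n_neighbors in UMAP -
is exposed under a single name and swept over (15, 25, 50) by default,
giving a 2 x 3 panel of views.

``mixing_score`` is the numeric twin of the visual overlap judgment:
the mean, over synthetic points, of the fraction of k nearest 2-D
neighbors that are real.  Under perfect mixing it sits near the real
fraction of the pool; complete real/synthetic separation drives it to 0,
and mode collapse (dense synthetic clouds) pulls it down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .distances import DistanceMatrix

__all__ = ["ProjectionResult", "project", "sweep", "mixing_score", "plot_projection"]

DEFAULT_NEIGHBOR_VALUES = (15, 25, 50)


@dataclass
class ProjectionResult:
    method: str  # "tsne" | "umap"
    n_neighbors: int
    coords: np.ndarray  # (n, 2)
    origins: list[str]
    ids: list[str]
    seed: int

    def __post_init__(self):
        if self.coords.shape != (len(self.origins), 2):
            raise ValueError("coordinate count must equal pooled record count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projection produced non-finite coordinates")


def project(
    dmatrix: DistanceMatrix, method: str, n_neighbors: int, seed: int
) -> ProjectionResult:
    """Embed a precomputed distance matrix in 2-D with tSNE or UMAP."""
    n = dmatrix.n
    if not 2 <= n_neighbors < n:
        raise ValueError(f"n_neighbors must be in [2, {n}), got {n_neighbors}")
    if method == "tsne":
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=n_neighbors,
            random_state=seed,
        )
        coords = tsne.fit_transform(dmatrix.combined)
    elif method == "umap":
        import umap  # deferred: numba compilation on first import

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap warns about precomputed+random_state
            reducer = umap.UMAP(
                n_components=2,
                metric="precomputed",
                n_neighbors=n_neighbors,
                init="random",
                random_state=seed,
            )
            coords = reducer.fit_transform(dmatrix.combined)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProjectionResult(
        method=method,
        n_neighbors=n_neighbors,
        coords=np.asarray(coords, dtype=float),
        origins=list(dmatrix.origins),
        ids=list(dmatrix.ids),
        seed=seed,
    )


def sweep(
    dmatrix: DistanceMatrix,
    methods: Sequence[str] = ("tsne", "umap"),
    neighbor_values: Sequence[int] = DEFAULT_NEIGHBOR_VALUES,
    seed: int = 0,
) -> list[ProjectionResult]:
    """One projection per (method, neighbor value); 6 panels by default."""
    return [project(dmatrix, m, nv, seed) for m in methods for nv in neighbor_values]


def mixing_score(result: ProjectionResult, k: int, synthetic_tag: str = "synthetic") -> float:
    """Mean fraction of real points among each synthetic point's k nearest 2-D neighbors."""
    origins = np.asarray(result.origins)
    is_synth = origins == synthetic_tag
    if not is_synth.any() or is_synth.all():
        raise ValueError("mixing score needs both synthetic and real points")
    n = len(origins)
    if k >= n:
        raise ValueError(f"k must be < {n}, got {k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(result.coords)
    _, idx = nn.kneighbors(result.coords[is_synth])
    query_idx = np.flatnonzero(is_synth)
    fracs = []
    for q, neigh in zip(query_idx, idx):
        others = [j for j in neigh if j != q][:k]
        fracs.append(np.mean(~is_synth[others]))
    return float(np.mean(fracs))


def plot_projection(result: ProjectionResult, path, synthetic_tag: str = "synthetic") -> None:
    """Scatter plot with real points drawn under synthetic points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    origins = np.asarray(result.origins)
    is_synth = origins == synthetic_tag
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(*result.coords[~is_synth].T, s=6, alpha=0.6, label="real", color="#4878d0")
    ax.scatter(*result.coords[is_synth].T, s=6, alpha=0.6, label="synthetic", color="#ee854a")
    ax.set_title(f"{result.method}, neighbors={result.n_neighbors}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
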