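"""Data augmentation: artificial doublets and the preliminary knn score.

Artificial doublets are built by summing two randomly chosen input cells and
rescaling the sum to a library size drawn from the real cells whose library
size is at least as large as the larger parent.  A preliminary doublet score
per augmented row — the fraction of simulated doublets among its nearest
neighbors in PCA space — then drives both the estimate of how many real
doublets the data contains and a score-weighted subsampling of the simulated
set down to that estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import CountMatrix, TransformedMatrix
from ._pca import project_pcs

log = logging.getLogger("vaeda")

__all__ = [
    "AugmentedSet",
    "simulate_doublets",
    "default_knn_k",
    "preliminary_knn_scores",
    "estimate_num_doublets",
    "subsample_doublets",
]


@dataclass
class AugmentedSet:
    """Stacked real + simulated expression rows with per-row bookkeeping.

    ``labels`` holds ``n_real`` zeros followed by ``n_sim`` ones; ``parents``
    gives, for each simulated row, the index pair of its two real parent
    cells; ``prelim_scores`` is the knn doublet-fraction score in [0, 1].
    """

    matrix: np.ndarray
    labels: np.ndarray
    parents: np.ndarray
    prelim_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n_sim = int(self.labels.sum())
        n_real = self.labels.size - n_sim
        if not (np.all(self.labels[:n_real] == 0) and np.all(self.labels[n_real:] == 1)):
            raise ValueError("labels must be n_real zeros followed by n_sim ones")
        if self.matrix.shape[0] != self.labels.size:
            raise ValueError("matrix rows and labels disagree")
        self.parents = np.asarray(self.parents)
        if self.parents.shape != (n_sim, 2):
            raise ValueError("parents must be (n_sim, 2)")
        if n_sim and (self.parents.min() < 0 or self.parents.max() >= n_real):
            raise ValueError("parent indices must point at real rows")
        if self.prelim_scores is not None:
            s = np.asarray(self.prelim_scores, dtype=np.float64)
            if s.shape != (self.labels.size,):
                raise ValueError("prelim_scores must align with rows")
            if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
                raise ValueError("prelim_scores must lie in [0, 1]")
            self.prelim_scores = np.clip(s, 0.0, 1.0)

    @property
    def n_real(self) -> int:
        return int(self.labels.size - self.labels.sum())

    @property
    def n_sim(self) -> int:
        return int(self.labels.sum())


def simulate_doublets(
    X: CountMatrix,
    n_sim: int | None = None,
    rng_seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> tuple[CountMatrix, np.ndarray]:
    """Simulate ``n_sim`` artificial doublets (default: one per input cell).

    For each doublet an index pair (i, j), i != j, is drawn uniformly; the
    precursor is row_i + row_j; its target library size is a uniform draw
    (with replacement) from the real library sizes that are >= the larger
    parent library size; the doublet is the precursor rescaled to that size.
    Rescaled rows are kept as reals.  Returns the simulated rows and the
    retained (n_sim, 2) parent-index array.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = X.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to simulate doublets")
    if n_sim is None:
        n_sim = n
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")

    libsizes = X.library_sizes
    order = np.sort(libsizes)

    pairs = np.empty((n_sim, 2), dtype=np.int64)
    rows = np.empty((n_sim, X.n_genes), dtype=np.float64)
    for d in range(n_sim):
        for attempt in range(max_retries):
            i, j = rng.choice(n, size=2, replace=False)
            precursor = X.counts[i] + X.counts[j]
            total = precursor.sum()
            if total > 0:
                break
        else:
            raise RuntimeError("could not draw a parent pair with positive total count")
        larger = max(libsizes[i], libsizes[j])
        lo = np.searchsorted(order, larger, side="left")
        ell = order[rng.integers(lo, n)]  # eligible multiset always contains `larger`
        rows[d] = ell * precursor / total
        pairs[d] = (i, j)

    barcodes = [f"sim-doublet-{d}" for d in range(n_sim)]
    return CountMatrix(counts=rows, barcodes=barcodes, genes=list(X.genes)), pairs


def default_knn_k(n_rows: int) -> int:
    """Neighborhood size for the preliminary score: ceil(sqrt(#rows))."""
    return max(1, math.ceil(math.sqrt(n_rows)))


def preliminary_knn_scores(
    M: TransformedMatrix | np.ndarray,
    labels: np.ndarray,
    k: int | None = None,
    n_pcs: int = 30,
    rng_seed: int = 0,
) -> np.ndarray:
    """Fraction of simulated doublets among each row's k nearest neighbors.

    Rows are projected on the first ``n_pcs`` principal components and a
    Euclidean knn graph (self excluded) is built; the score of a row is the
    mean label of its neighbors.
    """
    values = M.values if isinstance(M, TransformedMatrix) else np.asarray(M, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    n = values.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with matrix rows")
    if k is None:
        k = default_knn_k(n)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")

    pcs = project_pcs(values, n_pcs=n_pcs, rng_seed=rng_seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    idx = idx[:, 1:]  # drop self (nearest neighbor of itself at distance 0)
    return labels[idx].mean(axis=1)


def estimate_num_doublets(
    s: np.ndarray, labels: np.ndarray, quantile: float = 0.25
) -> int:
    """Estimate the number of real doublets among the input cells.

    The cutoff is the given quantile (linear-interpolation convention) of the
    simulated doublets' preliminary scores; the estimate is the number of
    real cells scoring at or above the cutoff.
    """
    s = np.asarray(s, dtype=np.float64)
    labels = np.asarray(labels)
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    sim = s[labels == 1]
    real = s[labels == 0]
    if sim.size == 0 or real.size == 0:
        raise ValueError("need at least one simulated and one real row")
    cutoff = np.quantile(sim, quantile)  # linear interpolation between order stats
    return int(np.sum(real >= cutoff))


def subsample_doublets(
    sim_scores: np.ndarray,
    n_hat: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Pick ``n_hat`` simulated rows without replacement, P(row) ∝ score.

    If fewer than ``n_hat`` rows have a positive score, all of them are taken
    and the shortfall is drawn uniformly from the zero-score rows.  Returns
    sorted row indices into the simulated set.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    s = np.asarray(sim_scores, dtype=np.float64)
    if s.size and s.min() < 0:
        raise ValueError("scores must be non-negative")
    n_sim = s.size
    if not 0 <= n_hat <= n_sim:
        raise ValueError(f"n_hat must be in [0, {n_sim}]")
    if n_hat == 0:
        return np.empty(0, dtype=np.int64)
    positive = np.flatnonzero(s > 0)
    zero = np.flatnonzero(s == 0)
    if n_hat <= positive.size:
        chosen = rng.choice(positive, size=n_hat, replace=False, p=s[positive] / s[positive].sum())
    else:
        extra = rng.choice(zero, size=n_hat - positive.size, replace=False)
        chosen = np.concatenate([positive, extra])
    return np.sort(chosen).astype(np.int64)
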