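"""End-to-end doublet-annotation pipeline and evaluation statistics.

``run_pipeline`` chains the stages in method order — doublet simulation,
gene filtering/selection, preliminary knn scoring, doublet-count estimation
and subsampling, Leiden clustering with homotypic exclusion, the
cluster-aware VAE embedding, PU bagging, and threshold-based calling — and
returns one score and one binary call per input barcode.  A single global
seed fans out to every stochastic stage, so runs are bit-reproducible on a
single thread.

The evaluation helpers compute average precision against ground truth, the
leave-one-out knn label-preservation accuracies comparing input space to the
latent space, and the per-doublet singlet fraction among nearest neighbors
(homotypic doublets sit among singlets of their own type and show higher
fractions).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score
from sklearn.neighbors import NearestNeighbors

from . import augment, caller, clustering, io_preprocess, pu_learn, vae
from .io_preprocess import CountMatrix, TransformedMatrix, log_standardize
from .pu_learn import PUConfig, PUFeatures
from .vae import LatentEmbedding, VaeConfig

log = logging.getLogger("vaeda")

__all__ = [
    "PipelineConfig",
    "DoubletResult",
    "run_pipeline",
    "average_precision",
    "knn_label_preservation",
    "singlet_fraction_neighborhood",
]

_MIN_POSITIVES = 5  # PU bagging needs a non-trivial positive set


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one global seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class PipelineConfig:
    seed: int = 0
    # preprocessing
    max_zero_fraction: float = 0.99
    n_top_genes: int = 2000
    # augmentation
    n_sim: int | None = None  # default: one simulated doublet per input cell
    knn_k: int | None = None  # default: ceil(sqrt(#augmented rows))
    n_pcs: int = 30
    quantile: float = 0.25
    # clustering
    small_threshold: int = 1000
    meta_fraction: float = 0.10
    n_neighbors: int = 15
    resolution: float = 1.0
    # model configs (rng seeds are overwritten from the global seed)
    vae: VaeConfig = field(default_factory=VaeConfig)
    pu: PUConfig = field(default_factory=PUConfig)
    # calling
    expected_doublets: float | None = None  # user-supplied mu
    make_calls: bool = True


@dataclass
class DoubletResult:
    """Per-barcode doublet scores and calls plus pipeline by-products."""

    barcodes: list[str]
    scores: np.ndarray  # xi, one per input barcode
    calls: np.ndarray | None
    threshold: float | None
    n_doublets_estimated: int
    mu: float | None
    sigma: float | None
    latent: LatentEmbedding  # input cells only
    scores_sim: np.ndarray  # side scores of surviving simulated doublets
    input_representation: TransformedMatrix  # VAE input restricted to input cells
    report: dict


def run_pipeline(X: CountMatrix, cfg: PipelineConfig | None = None) -> DoubletResult:
    cfg = cfg or PipelineConfig()
    seeds = _derive_seeds(cfg.seed, 6)
    t0 = time.time()
    n = X.n_cells
    report: dict = {"n_cells": n, "n_genes": X.n_genes, "seed": cfg.seed, "stages": {}}

    # -- augmentation (simulate doublets, stack, select genes) --------------
    sim, parents = augment.simulate_doublets(X, n_sim=cfg.n_sim, rng_seed=seeds[0])
    n_sim = sim.n_cells
    aug = CountMatrix(
        counts=np.vstack([X.counts, sim.counts]),
        barcodes=list(X.barcodes) + list(sim.barcodes),
        genes=list(X.genes),
    )
    labels = np.concatenate([np.zeros(n, np.int8), np.ones(n_sim, np.int8)])
    aug = io_preprocess.filter_sparse_genes(aug, cfg.max_zero_fraction)
    aug = io_preprocess.select_variable_genes(aug, cfg.n_top_genes)
    log.info("augmented matrix: %d cells + %d simulated, %d genes", n, n_sim, aug.n_genes)
    report["stages"]["augment"] = {"n_sim": n_sim, "n_genes_kept": aug.n_genes}

    # -- preliminary knn score and doublet-count estimate -------------------
    col_std = log_standardize(aug, axis="columns")
    s = augment.preliminary_knn_scores(
        col_std, labels, k=cfg.knn_k, n_pcs=cfg.n_pcs, rng_seed=seeds[1]
    )
    n_hat = augment.estimate_num_doublets(s, labels, quantile=cfg.quantile)
    n_keep = min(max(n_hat, _MIN_POSITIVES), n_sim)
    if n_keep != n_hat:
        log.warning("adjusted retained simulated doublets from %d to %d", n_hat, n_keep)
    sel = augment.subsample_doublets(s[labels == 1], n_keep, rng_seed=seeds[2])
    log.info("estimated %d doublets among %d cells; keeping %d simulated", n_hat, n, n_keep)
    report["stages"]["estimate"] = {"n_hat": n_hat, "n_kept": n_keep}

    sim_rows = n + sel  # row indices of selected simulated doublets in `aug`
    matrix = np.vstack([aug.counts[:n], aug.counts[sim_rows]])
    s = np.concatenate([s[:n], s[sim_rows]])
    labels = np.concatenate([np.zeros(n, np.int8), np.ones(len(sel), np.int8)])
    parents = parents[sel]

    # -- clustering and homotypic exclusion ---------------------------------
    row_std = log_standardize(matrix, axis="rows")
    clabels = clustering.cluster_cells(
        row_std,
        small_threshold=cfg.small_threshold,
        meta_fraction=cfg.meta_fraction,
        n_pcs=cfg.n_pcs,
        n_neighbors=cfg.n_neighbors,
        resolution=cfg.resolution,
        rng_seed=seeds[3],
    )
    keep_sim = clustering.exclude_homotypic(parents, clabels, labels)
    if not keep_sim.any():
        raise RuntimeError(
            "all simulated doublets are homotypic (parents always share a cluster): "
            "doublet simulation collapsed, likely because the data has a single cell type"
        )
    keep_rows = np.concatenate([np.ones(n, bool), keep_sim])
    matrix, s, labels = matrix[keep_rows], s[keep_rows], labels[keep_rows]
    assignments = clabels.assignments[keep_rows]
    _, assignments = np.unique(assignments, return_inverse=True)
    clabels = clustering.ClusterLabels(assignments, int(assignments.max()) + 1)
    n_surviving = int(labels.sum())
    log.info(
        "clustering: %d clusters; homotypic exclusion kept %d/%d simulated doublets",
        clabels.n_clusters, n_surviving, keep_sim.size,
    )
    report["stages"]["clustering"] = {
        "n_clusters": clabels.n_clusters, "n_sim_surviving": n_surviving,
    }

    # -- cluster-aware VAE embedding ----------------------------------------
    vae_cfg = VaeConfig(**{**cfg.vae.__dict__, "rng_seed": seeds[4]})
    vae_input = log_standardize(matrix, axis="columns")
    model, history = vae.train(vae_input, clabels, vae_cfg)
    Z = vae.embed(model, vae_input)
    report["stages"]["vae"] = {
        "epochs_run": len(history["train_loss"]),
        "final_val_loss": history["val_loss"][-1],
    }

    # -- PU bagging ----------------------------------------------------------
    pu_cfg = PUConfig(**{**cfg.pu.__dict__, "rng_seed": seeds[5]})
    features = PUFeatures(Zbar=np.column_stack([Z.Z, s]), labels=labels)
    pu_res = pu_learn.pu_bagging(features, pu_cfg)
    xi = pu_res.scores_unlabeled
    report["stages"]["pu"] = {"epochs_used": pu_res.epochs_used}

    # -- calling -------------------------------------------------------------
    calls = threshold = mu = sigma = None
    if cfg.make_calls:
        mu, sigma = caller.expected_doublets(n, cfg.expected_doublets)
        result = caller.call_doublets(xi, pu_res.scores_positive, mu, sigma)
        calls, threshold = result.calls, result.threshold
        log.info("called %d/%d cells as doublets at t*=%.4f (mu=%.1f)", result.n_called, n, threshold, mu)
        report["stages"]["caller"] = {
            "threshold": threshold, "n_called": result.n_called, "mu": mu, "sigma": sigma,
        }
    report["runtime_seconds"] = round(time.time() - t0, 2)

    return DoubletResult(
        barcodes=list(X.barcodes),
        scores=xi,
        calls=calls,
        threshold=threshold,
        n_doublets_estimated=n_hat,
        mu=mu,
        sigma=sigma,
        latent=LatentEmbedding(Z=Z.Z[:n], source=Z.source),
        scores_sim=pu_res.scores_positive,
        input_representation=TransformedMatrix(
            values=vae_input.values[:n], transform_tag=vae_input.transform_tag
        ),
        report=report,
    )


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------


def average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    return float(average_precision_score(truth, np.asarray(scores, dtype=np.float64)))


def _loo_knn_accuracy(values: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Leave-one-out k-nearest-neighbor majority-vote accuracy."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(values)
    _, idx = nn.kneighbors(values)
    votes = truth[idx[:, 1:]].mean(axis=1)
    predicted = votes > 0.5  # k odd => no ties for binary labels
    return float((predicted == truth).mean())


def knn_label_preservation(
    M_input: TransformedMatrix | np.ndarray,
    Z: LatentEmbedding | np.ndarray,
    truth: np.ndarray,
    k: int = 5,
) -> tuple[float, float]:
    """LOO knn(k) truth-label accuracy in input space and in latent space."""
    x = M_input.values if isinstance(M_input, TransformedMatrix) else np.asarray(M_input)
    z = Z.Z if isinstance(Z, LatentEmbedding) else np.asarray(Z)
    truth = np.asarray(truth, dtype=bool)
    if x.shape[0] != truth.size or z.shape[0] != truth.size:
        raise ValueError("representations and truth must be row-aligned")
    return _loo_knn_accuracy(x, truth, k), _loo_knn_accuracy(z, truth, k)


def singlet_fraction_neighborhood(
    Z: LatentEmbedding | np.ndarray, truth: np.ndarray, k: int = 5
) -> np.ndarray:
    """For every true doublet, the singlet fraction among its k nearest neighbors."""
    z = Z.Z if isinstance(Z, LatentEmbedding) else np.asarray(Z)
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise ValueError("no true doublets in truth vector")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, idx = nn.kneighbors(z[truth])
    # drop each query itself if it appears among its own neighbors
    rows = []
    doublet_rows = np.flatnonzero(truth)
    for q, neigh in zip(doublet_rows, idx):
        neigh = neigh[neigh != q][:k]
        rows.append(1.0 - truth[neigh].mean())
    return np.asarray(rows)
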