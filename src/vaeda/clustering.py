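"""Leiden clustering of the augmented data and homotypic-doublet exclusion.

Small datasets are clustered directly: project the row-standardized matrix on
its leading principal components, build a k-nearest-neighbor graph and run
Leiden community detection.  Larger datasets are first condensed into
meta-cells with mini-batch k-means (k = 10% of rows); the meta-cells are
clustered the same way and every cell inherits its meta-cell's label.

A simulated doublet whose two parent cells fall in the same cluster is
"homotypic" — it resembles a singlet of that type and would poison the
positive set — and is removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from sklearn.cluster import MiniBatchKMeans
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import TransformedMatrix
from ._pca import project_pcs

log = logging.getLogger("vaeda")

__all__ = ["ClusterLabels", "cluster_cells", "exclude_homotypic"]


@dataclass
class ClusterLabels:
    """Per-row cluster assignment with contiguous labels 0..n_clusters-1."""

    assignments: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        present = np.unique(self.assignments)
        if not np.array_equal(present, np.arange(self.n_clusters)):
            raise ValueError("labels must be contiguous 0..n_clusters-1, each present")


def _leiden_on_knn(
    pcs: np.ndarray, n_neighbors: int, resolution: float, rng_seed: int
) -> np.ndarray:
    """Distance-weighted undirected knn graph (self excluded) + Leiden.

    Edge weights are a Gaussian kernel of the Euclidean distance with
    bandwidth set to the mean edge distance, so that when k is large relative
    to the node count (tiny graphs, meta-cells) spurious long edges carry
    negligible weight and real structure still dominates the partition.
    """
    n = pcs.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    edges: dict[tuple[int, int], float] = {}
    for a, row, drow in zip(range(n), idx[:, 1:], dist[:, 1:]):
        for b, d in zip(row, drow):
            key = (a, int(b)) if a < b else (int(b), a)
            edges[key] = min(edges.get(key, np.inf), float(d))
    keys = sorted(edges)
    dists = np.array([edges[k_] for k_ in keys])
    bandwidth = dists.mean() if dists.size and dists.mean() > 0 else 1.0
    weights = np.exp(-((dists / bandwidth) ** 2))
    graph = igraph.Graph(n=n, edges=keys, directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights.tolist(),
        resolution_parameter=resolution,
        seed=rng_seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.int64)


def cluster_cells(
    M: TransformedMatrix | np.ndarray,
    small_threshold: int = 1000,
    meta_fraction: float = 0.10,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    rng_seed: int = 0,
) -> ClusterLabels:
    """Cluster augmented rows with Leiden, via meta-cells for large inputs.

    Rows <= ``small_threshold``: PCA -> knn graph -> Leiden directly.
    Otherwise mini-batch k-means with k = ceil(meta_fraction * rows) forms
    meta-cells (centroids); the meta-cells are projected, graphed and
    Leiden-clustered, and each cell receives its meta-cell's label.
    """
    values = M.values if isinstance(M, TransformedMatrix) else np.asarray(M, dtype=np.float64)
    n = values.shape[0]
    pcs = project_pcs(values, n_pcs=n_pcs, rng_seed=rng_seed)

    if n <= small_threshold:
        membership = _leiden_on_knn(pcs, n_neighbors, resolution, rng_seed)
    else:
        k_meta = math.ceil(meta_fraction * n)
        km = MiniBatchKMeans(n_clusters=k_meta, random_state=rng_seed, n_init=3)
        cell_to_meta = km.fit_predict(pcs)
        used, cell_to_meta = np.unique(cell_to_meta, return_inverse=True)  # drop empty centroids
        centroids = km.cluster_centers_[used]
        meta_pcs = project_pcs(centroids, n_pcs=n_pcs, rng_seed=rng_seed)
        meta_membership = _leiden_on_knn(meta_pcs, n_neighbors, resolution, rng_seed)
        membership = meta_membership[cell_to_meta]

    _, membership = np.unique(membership, return_inverse=True)
    n_clusters = int(membership.max()) + 1
    if n_clusters == 1:
        log.warning("Leiden found a single cluster; homotypic exclusion will drop all doublets")
    return ClusterLabels(assignments=membership, n_clusters=n_clusters)


def exclude_homotypic(
    parents: np.ndarray, c: ClusterLabels, labels: np.ndarray
) -> np.ndarray:
    """Keep-mask over simulated rows: drop a doublet iff its parents share a cluster.

    ``c`` covers all augmented rows; only the clusters of the *real* parent
    cells matter, never the simulated row's own cluster.
    """
    labels = np.asarray(labels)
    parents = np.asarray(parents)
    n_real = int(labels.size - labels.sum())
    if c.assignments.size != labels.size:
        raise ValueError("cluster labels must cover all augmented rows")
    real_clusters = c.assignments[:n_real]
    keep = real_clusters[parents[:, 0]] != real_clusters[parents[:, 1]]
    return keep
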