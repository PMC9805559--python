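"""Shared PCA projection helper.

Exact SVD for matrices up to 5,000 rows, seeded randomized SVD above — the
switch keeps small problems bit-stable while staying tractable on large ones.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.decomposition import PCA

log = logging.getLogger("vaeda")

EXACT_SVD_MAX_ROWS = 5000


def project_pcs(values: np.ndarray, n_pcs: int = 30, rng_seed: int = 0) -> np.ndarray:
    """Project rows of ``values`` onto their first ``n_pcs`` principal components."""
    n, p = values.shape
    max_pcs = min(n - 1, p)
    if n_pcs > max_pcs:
        log.warning("reducing n_pcs from %d to %d (matrix is %dx%d)", n_pcs, max_pcs, n, p)
        n_pcs = max(1, max_pcs)
    solver = "full" if n <= EXACT_SVD_MAX_ROWS else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=rng_seed)
    return pca.fit_transform(values)
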