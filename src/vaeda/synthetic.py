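"""Synthetic multi-cell-type scRNA-seq counts with ground-truth doublets.

Generates negative-binomial UMI counts for a configurable number of cell
types: every type shares a lognormal baseline expression profile but gets a
block of marker genes up-regulated by ``type_mean_scale``.  Library sizes
are lognormal.  Doublets are injected by summing the counts of two freshly
drawn parent cells — from different types (heterotypic) for most, from the
same type for a configurable homotypic fraction — mirroring how real
droplet doublets superimpose two transcriptomes with roughly additive
library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_preprocess import CountMatrix

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset"]


@dataclass
class SyntheticSpec:
    n_singlets: int = 2000
    n_genes: int = 1500
    n_types: int = 5
    doublet_rate: float = 0.10
    type_mean_scale: float = 10.0
    nb_dispersion: float = 2.0
    libsize_meanlog: float = math.log(2500.0)
    libsize_sdlog: float = 0.35
    homotypic_fraction: float = 0.2  # fraction of injected doublets that are same-type
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must be in [0, 1)")
        if not 0.0 <= self.homotypic_fraction <= 1.0:
            raise ValueError("homotypic_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    is_doublet: np.ndarray  # truth over rows
    cell_type: np.ndarray  # singlet type, or the first parent's type for doublets
    homotypic: np.ndarray  # over rows; True only for same-type injected doublets


def _type_profiles(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-type relative expression profiles (rows sum to 1)."""
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    profiles = np.tile(baseline, (spec.n_types, 1))
    markers_per_type = max(1, spec.n_genes // (2 * spec.n_types))
    for t in range(spec.n_types):
        block = slice(t * markers_per_type, (t + 1) * markers_per_type)
        profiles[t, block] *= spec.type_mean_scale
    return profiles / profiles.sum(axis=1, keepdims=True)


def _draw_cells(
    types: np.ndarray, profiles: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """NB counts via the gamma-Poisson mixture, one row per entry of ``types``."""
    lib = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=types.size)
    mean = lib[:, None] * profiles[types]
    theta = spec.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam).astype(np.float64)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate counts plus truth labels; seeded generation is bit-reproducible.

    Row count is n_singlets + round(doublet_rate * n_singlets / (1 - doublet_rate)),
    so doublets make up ``doublet_rate`` of all barcodes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    profiles = _type_profiles(spec, rng)

    singlet_types = rng.integers(0, spec.n_types, size=spec.n_singlets)
    singlets = _draw_cells(singlet_types, profiles, spec, rng)

    n_dbl = int(round(spec.doublet_rate * spec.n_singlets / (1.0 - spec.doublet_rate)))
    homotypic = rng.random(n_dbl) < spec.homotypic_fraction
    t1 = rng.integers(0, spec.n_types, size=n_dbl)
    t2 = np.where(
        homotypic, t1, (t1 + 1 + rng.integers(0, spec.n_types - 1, size=n_dbl)) % spec.n_types
    )
    doublets = _draw_cells(t1, profiles, spec, rng) + _draw_cells(t2, profiles, spec, rng)

    counts = np.vstack([singlets, doublets]) if n_dbl else singlets
    # a zero row is essentially impossible at realistic library sizes; resample if hit
    for i in np.flatnonzero(counts.sum(axis=1) == 0):
        while counts[i].sum() == 0:  # pragma: no cover
            counts[i] = _draw_cells(np.array([singlet_types[i % spec.n_singlets]]), profiles, spec, rng)[0]

    barcodes = [f"cell-{i}" for i in range(spec.n_singlets)] + [f"dbl-{i}" for i in range(n_dbl)]
    genes = [f"gene-{g}" for g in range(spec.n_genes)]
    cm = CountMatrix(counts=counts, barcodes=barcodes, genes=genes)
    is_doublet = np.concatenate([np.zeros(spec.n_singlets, bool), np.ones(n_dbl, bool)])
    cell_type = np.concatenate([singlet_types, t1]).astype(np.int64)
    homo_full = np.concatenate([np.zeros(spec.n_singlets, bool), homotypic])
    return SyntheticDataset(counts=cm, is_doublet=is_doublet, cell_type=cell_type, homotypic=homo_full)
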