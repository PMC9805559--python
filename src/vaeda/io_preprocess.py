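"""Count-matrix loading, gene filtering/selection and log-standardization.

The pipeline ingests a raw, un-normalized UMI count matrix with cells as rows
and genes as columns, from a 10x-style MTX directory, an ``.h5ad`` container,
or a plain CSV.  Downstream stages consume two derived representations:
raw-count submatrices after sparse-gene removal and highly-variable-gene
selection, and log1p + z-scored transforms (by column or by row).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "TransformedMatrix",
    "load_counts",
    "write_mtx",
    "filter_sparse_genes",
    "select_variable_genes",
    "log_standardize",
]


@dataclass
class CountMatrix:
    """Expression matrix with cells as rows and genes as columns.

    ``counts`` holds raw UMIs for input cells; simulated doublet rows are
    library-size-rescaled sums of two cells and may therefore be non-integer
    reals.  Entries must be non-negative and finite, and identifier lists
    must match the matrix shape without duplicates.  Loading additionally
    rejects barcodes with zero library size (total count).
    """

    counts: np.ndarray
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (cells x genes)")
        n, p = self.counts.shape
        if len(self.barcodes) != n:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n} rows")
        if len(self.genes) != p:
            raise ValueError(f"{len(self.genes)} gene ids for {p} columns")
        if len(set(self.barcodes)) != n:
            raise ValueError("duplicate barcodes")
        if len(set(self.genes)) != p:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts contain negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class TransformedMatrix:
    """Real-valued transform of a count matrix, tagged with its convention."""

    values: np.ndarray
    transform_tag: str  # "log-scaled" | "column-standardized" | "row-standardized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        allowed = {"log-scaled", "column-standardized", "row-standardized"}
        if self.transform_tag not in allowed:
            raise ValueError(f"transform_tag must be one of {sorted(allowed)}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.txt")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.txt")
_FEATURE_NAMES = ("features.tsv", "genes.tsv", "features.txt", "genes.txt")


def _find_file(directory: str, candidates: tuple[str, ...], what: str) -> str:
    for name in candidates:
        path = os.path.join(directory, name)
        if os.path.exists(path):
            return path
    raise FileNotFoundError(f"no {what} file in {directory} (looked for {', '.join(candidates)})")


def _read_id_column(path: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _coerce_counts(dense: np.ndarray, where: str) -> np.ndarray:
    if not np.all(np.isfinite(dense)):
        raise ValueError(f"{where}: non-finite count entries")
    if dense.size and dense.min() < 0:
        raise ValueError(f"{where}: negative count entries")
    rounded = np.rint(dense)
    if not np.allclose(dense, rounded, atol=1e-8):
        raise ValueError(f"{where}: non-integer count entries")
    return rounded


def load_counts(path: str, format: str | None = None) -> CountMatrix:
    """Load a raw count matrix from disk.

    Parameters
    ----------
    path
        MTX directory, ``.h5ad`` file, or CSV file.
    format
        One of ``"mtx_dir"``, ``"h5_container"``, ``"csv"``; inferred from
        ``path`` when omitted.

    Genes come back as columns regardless of the on-disk orientation; for MTX
    the orientation is detected from the features-file length (10x writes
    genes x cells).  Counts are validated to be non-negative integers.
    """
    if format is None:
        if os.path.isdir(path):
            format = "mtx_dir"
        elif path.endswith((".h5ad", ".h5")):
            format = "h5_container"
        elif path.endswith(".csv"):
            format = "csv"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format explicitly")

    if format == "mtx_dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(f"not a directory: {path}")
        mtx = _find_file(path, _MTX_NAMES, "matrix")
        barcodes = _read_id_column(_find_file(path, _BARCODE_NAMES, "barcodes"))
        genes = _read_id_column(_find_file(path, _FEATURE_NAMES, "features"))
        mat = scipy.io.mmread(mtx)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
        if dense.shape == (len(genes), len(barcodes)) and dense.shape != (len(barcodes), len(genes)):
            dense = dense.T  # 10x convention: genes x cells on disk
        elif dense.shape == (len(barcodes), len(genes)):
            pass
        elif dense.shape[0] == dense.shape[1] == len(genes) == len(barcodes):
            dense = dense.T  # square and ambiguous: assume the 10x convention
        else:
            raise ValueError(
                f"matrix shape {dense.shape} matches neither (cells={len(barcodes)}, "
                f"genes={len(genes)}) nor its transpose"
            )
        counts = _coerce_counts(dense, mtx)
    elif format == "h5_container":
        import anndata

        if not os.path.exists(path):
            raise FileNotFoundError(path)
        adata = anndata.read_h5ad(path)
        x = adata.X
        dense = np.asarray(x.todense() if scipy.sparse.issparse(x) else x, dtype=np.float64)
        counts = _coerce_counts(dense, path)
        barcodes = adata.obs_names.tolist()
        genes = adata.var_names.tolist()
    elif format == "csv":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        df = pd.read_csv(path, index_col=0)
        counts = _coerce_counts(df.to_numpy(dtype=np.float64), path)
        barcodes = [str(b) for b in df.index]
        genes = [str(g) for g in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    if counts.size and np.any(counts.sum(axis=1) == 0):
        bad = [barcodes[i] for i in np.flatnonzero(counts.sum(axis=1) == 0)[:5]]
        raise ValueError(f"rows with zero library size (e.g. {bad}); remove empty barcodes first")
    return CountMatrix(counts=counts, barcodes=barcodes, genes=genes)


def write_mtx(cm: CountMatrix, directory: str) -> None:
    """Write a CountMatrix as a 10x-style MTX directory (genes x cells)."""
    os.makedirs(directory, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(cm.counts.T)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), sparse, field="integer")
    pd.DataFrame({0: cm.barcodes}).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    pd.DataFrame({0: cm.genes, 1: cm.genes, 2: "Gene Expression"}).to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Gene filtering and selection
# ---------------------------------------------------------------------------


def filter_sparse_genes(X: CountMatrix, max_zero_fraction: float = 0.99) -> CountMatrix:
    """Drop genes that are zero in more than ``max_zero_fraction`` of rows.

    A gene whose zero-fraction equals the threshold exactly is retained
    (removal requires *more than* the allowed fraction of zeros).
    """
    if not 0.0 < max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    zero_frac = (X.counts == 0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError(
            "all genes exceed the zero-fraction threshold; the matrix is too sparse to analyse"
        )
    return CountMatrix(
        counts=X.counts[:, keep],
        barcodes=list(X.barcodes),
        genes=[g for g, k in zip(X.genes, keep) if k],
    )


def select_variable_genes(X: CountMatrix, n_top: int = 2000) -> CountMatrix:
    """Keep the ``n_top`` genes with the largest per-gene count variance.

    Variance is computed on raw counts (population convention).  Ties are
    broken by original gene order (first wins) and the selected genes keep
    their original relative order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top >= X.n_genes:
        return X
    variances = X.counts.var(axis=0)
    order = np.argsort(-variances, kind="stable")[:n_top]
    keep = np.sort(order)
    return CountMatrix(
        counts=X.counts[:, keep],
        barcodes=list(X.barcodes),
        genes=[X.genes[i] for i in keep],
    )


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------


def log_standardize(X: CountMatrix | np.ndarray, axis: str = "columns") -> TransformedMatrix:
    """log1p-transform and z-score along ``axis`` ("columns" or "rows").

    Uses the sample (ddof = 1) standard deviation, the single-cell scaling
    convention.  Constant slices (and length-1 slices) become all-zero
    instead of NaN, keeping dimensions stable.
    """
    if axis not in ("columns", "rows"):
        raise ValueError("axis must be 'columns' or 'rows'")
    values = X.counts if isinstance(X, CountMatrix) else np.asarray(X, dtype=np.float64)
    if values.size and values.min() < 0:
        raise ValueError("log_standardize requires non-negative values")
    logged = np.log1p(values)
    ax = 0 if axis == "columns" else 1
    mean = logged.mean(axis=ax, keepdims=True)
    if logged.shape[ax] < 2:
        return TransformedMatrix(
            values=np.zeros_like(logged),
            transform_tag="column-standardized" if axis == "columns" else "row-standardized",
        )
    sd = logged.std(axis=ax, ddof=1, keepdims=True)  # sample convention (ddof=1)
    out = np.where(sd > 0, (logged - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    tag = "column-standardized" if axis == "columns" else "row-standardized"
    return TransformedMatrix(values=out, transform_tag=tag)
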