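"""Core data containers, file I/O and preprocessing for multi-batch scRNA-seq.

The internal orientation is cells x genes everywhere; 10x-style genes x cells
input is transposed at read time. Counts are kept sparse (CSR, integer);
log-normalised expression is sparse float with the same sparsity pattern.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "CellMeta",
    "ExpressionMatrix",
    "CDRVector",
    "read_counts",
    "write_counts",
    "read_meta",
    "filter_cells",
    "lognormalize",
    "compute_cdr",
    "select_hvgs",
    "compute_pca",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected on-disk format."""


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        counts = pd.Series(ids).value_counts()
        dups = list(counts[counts > 1].index[:5])
        raise ValueError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes, with cell and gene identifiers.

    Parameters
    ----------
    counts
        Sparse or dense non-negative integer matrix, cells x genes.
    cell_ids, gene_ids
        Unique string identifiers matching the matrix dimensions.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        data = self.counts.data
        if data.size and not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if data.size and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts.eliminate_zeros()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes detected (nonzero) per cell."""
        return np.diff(self.counts.indptr)

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(self.counts[idx], self.cell_ids[idx], self.gene_ids)


@dataclass
class CellMeta:
    """Per-cell metadata aligned with a :class:`CountMatrix`.

    ``df`` has one row per cell (indexed by cell id) and must contain the batch
    column — the confounder that the similarity metric regresses out. Optional
    columns hold a curated annotation (assisted-mode input) and extra
    covariates such as donor or treatment.
    """

    df: pd.DataFrame
    batch_col: str = "batch"
    annotation_col: Optional[str] = None
    extra_cols: tuple = ()

    def __post_init__(self) -> None:
        if self.batch_col not in self.df.columns:
            raise ValueError(f"metadata lacks batch column {self.batch_col!r}")
        if self.annotation_col is not None and self.annotation_col not in self.df.columns:
            raise ValueError(f"metadata lacks annotation column {self.annotation_col!r}")
        for c in self.extra_cols:
            if c not in self.df.columns:
                raise ValueError(f"metadata lacks covariate column {c!r}")

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def batch(self) -> np.ndarray:
        return self.df[self.batch_col].astype(str).to_numpy()

    @property
    def annotation(self) -> np.ndarray:
        if self.annotation_col is None:
            raise ValueError("no annotation column configured")
        return self.df[self.annotation_col].to_numpy()

    def extras(self, idx: Optional[np.ndarray] = None) -> dict:
        """Extra covariate columns as name -> per-cell string array."""
        d = self.df if idx is None else self.df.iloc[idx]
        return {c: d[c].astype(str).to_numpy() for c in self.extra_cols}

    def subset(self, idx: np.ndarray) -> "CellMeta":
        return replace(self, df=self.df.iloc[np.asarray(idx)])


@dataclass
class ExpressionMatrix:
    """Log2-normalised expression, cells x genes, sparse.

    value[i, j] = log2(1 + scale * counts[i, j] / libsize_i); zeros stay zero,
    so the sparsity pattern equals that of the source counts.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match id lists")
        if self.values.data.size and not np.all(np.isfinite(self.values.data)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def genes_per_cell(self) -> np.ndarray:
        return np.diff(self.values.indptr)

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids,
            scale=self.scale, pseudocount=self.pseudocount,
        )

    def dense(self, cells: Optional[np.ndarray] = None,
              genes: Optional[np.ndarray] = None) -> np.ndarray:
        x = self.values
        if cells is not None:
            x = x[np.asarray(cells)]
        if genes is not None:
            x = x[:, np.asarray(genes)]
        return np.asarray(x.todense())


@dataclass
class CDRVector:
    """Cellular detection rate: genes detected per cell, raw and z-scored.

    ``scaled`` is standardised over the cells it was computed on (the cells
    entering one similarity comparison); zero spread gives all-zero scaled
    values.
    """

    raw: np.ndarray
    scaled: np.ndarray


# ---------------------------------------------------------------------------
# I/O


def _read_id_column(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty identifier file")
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_counts(matrix_path, genes_path=None, cells_path=None,
                orientation: str = "genes_by_cells") -> CountMatrix:
    """Read a count matrix from Matrix Market or dense delimited text.

    Parameters
    ----------
    matrix_path
        ``.mtx`` coordinate file (with ``genes_path``/``cells_path``
        one-column sidecars) or a dense TSV/CSV whose header row holds gene
        ids and whose first column holds cell ids.
    orientation
        ``"genes_by_cells"`` (10x convention; transposed on read) or
        ``"cells_by_genes"``. Applies to the MTX path only — a dense table's
        header always names the genes.

    Returns
    -------
    CountMatrix
        In internal cells x genes orientation.
    """
    matrix_path = Path(matrix_path)
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes_path and cells_path")
        try:
            mat = mmread(str(matrix_path))
        except Exception as exc:  # noqa: BLE001 - rewrap with file name
            raise FormatError(f"{matrix_path}: not a readable Matrix Market file ({exc})")
        mat = sp.coo_matrix(mat)
        if mat.shape[0] == 0 or mat.shape[1] == 0:
            raise FormatError(f"{matrix_path}: empty matrix")
        if not np.issubdtype(mat.dtype, np.integer):
            if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
                raise FormatError(f"{matrix_path}: non-integer entries")
            mat = mat.astype(np.int64)
        genes = _read_id_column(genes_path)
        cells = _read_id_column(cells_path)
        if orientation == "genes_by_cells":
            mat = mat.T
        if mat.shape[0] != len(cells):
            raise FormatError(
                f"{cells_path}: {len(cells)} cell ids for matrix with "
                f"{mat.shape[0]} cells"
            )
        if mat.shape[1] != len(genes):
            raise FormatError(
                f"{genes_path}: {len(genes)} gene ids for matrix with "
                f"{mat.shape[1]} genes"
            )
        return CountMatrix(mat.tocsr(), cells, genes)
    # dense delimited table: header = gene ids, first column = cell ids
    sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{matrix_path}: not a readable table ({exc})")
    if df.empty:
        raise FormatError(f"{matrix_path}: empty matrix")
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals.astype(float))):
        raise FormatError(f"{matrix_path}: non-integer entries")
    return CountMatrix(sp.csr_matrix(vals.astype(np.int64)),
                       df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object))


def write_counts(cm: CountMatrix, matrix_path, genes_path, cells_path,
                 orientation: str = "genes_by_cells") -> None:
    """Write counts as Matrix Market plus one-column id sidecars."""
    mat = cm.counts.T.tocoo() if orientation == "genes_by_cells" else cm.counts.tocoo()
    mmwrite(str(matrix_path), mat, field="integer")
    pd.Series(cm.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)


def read_meta(path, cm: Optional[CountMatrix] = None, batch_col: str = "batch",
              annotation_col: Optional[str] = None,
              extra_cols: Sequence[str] = ()) -> CellMeta:
    """Read a cell-metadata TSV (first column = cell id) aligned to ``cm``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if batch_col not in df.columns:
        raise FormatError(f"{path}: missing required column {batch_col!r}")
    if cm is not None:
        missing = set(cm.cell_ids) - set(df.index)
        if missing:
            raise FormatError(f"{path}: metadata missing {len(missing)} cells, "
                              f"e.g. {sorted(missing)[:3]}")
        df = df.loc[list(cm.cell_ids)]
    return CellMeta(df, batch_col=batch_col, annotation_col=annotation_col,
                    extra_cols=tuple(extra_cols))


# ---------------------------------------------------------------------------
# preprocessing


def filter_cells(cm: CountMatrix, meta: Optional[CellMeta], min_genes: int = 500):
    """Keep cells with at least ``min_genes`` detected genes.

    Metadata rows are subset in lockstep. Raises if no cell survives.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    keep = np.flatnonzero(cm.genes_per_cell() >= min_genes)
    if keep.size == 0:
        raise ValueError(
            f"no cells retain >= {min_genes} detected genes; lower min_genes"
        )
    out_meta = meta.subset(keep) if meta is not None else None
    return cm.subset_cells(keep), out_meta


def lognormalize(cm: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalise and log2 transform.

    value[i, j] = log2(1 + scale * counts[i, j] / libsize_i).
    """
    lib = np.asarray(cm.counts.sum(axis=1)).ravel().astype(float)
    if np.any(lib == 0):
        raise ValueError("all-zero cells present; run filter_cells first")
    x = sp.diags(scale / lib) @ cm.counts.astype(float)
    x = x.tocsr()
    x.data = np.log2(1.0 + x.data)
    return ExpressionMatrix(x, cm.cell_ids, cm.gene_ids, scale=scale, pseudocount=1.0)


def compute_cdr(x, within: Optional[np.ndarray] = None) -> CDRVector:
    """Cellular detection rate for the cells in ``within``.

    ``x`` may be a CountMatrix or ExpressionMatrix (detection pattern is the
    same). ``scaled`` is the z-score over the selected cells; zero standard
    deviation yields all-zero scaled values.
    """
    nnz = x.genes_per_cell()
    if within is None:
        raw = nnz.astype(float)
    else:
        within = np.asarray(within)
        if within.size == 0:
            raise ValueError("within must be non-empty")
        raw = nnz[within].astype(float)
    sd = raw.std()
    scaled = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
    return CDRVector(raw=raw, scaled=scaled)


def select_hvgs(em: ExpressionMatrix, n: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Rank genes by mean-binned standardized dispersion; return the top ``n`` ids.

    Dispersion = variance / mean of the log-normalised values; genes are
    grouped into ``n_bins`` equal-occupancy bins by mean, and the dispersion
    is z-scored within each bin. Ties are broken by gene id, making the
    ranking deterministic.
    """
    if n > em.n_genes:
        warnings.warn(f"requested {n} HVGs but only {em.n_genes} genes; using all")
        n = em.n_genes
    x = em.values
    ncell = em.n_cells
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = x.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean ** 2) * (ncell / max(ncell - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    bins = pd.qcut(mean, q=min(n_bins, max(1, len(np.unique(mean)))),
                   labels=False, duplicates="drop")
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        sd = disp[m].std()
        z[m] = 0.0 if sd == 0 else (disp[m] - disp[m].mean()) / sd
    order = np.lexsort((em.gene_ids, -z))
    return em.gene_ids[order[:n]]


def compute_pca(em: ExpressionMatrix, genes: Sequence[str],
                n_pcs: int = 10) -> np.ndarray:
    """PCA scores (cells x n_pcs) on the selected genes.

    Columns are ordered by decreasing explained variance. The sign of each
    component is fixed so that its largest-magnitude gene loading is positive,
    making repeated runs byte-comparable.
    """
    gene_pos = pd.Index(em.gene_ids).get_indexer(list(genes))
    if np.any(gene_pos < 0):
        missing = [g for g, p in zip(genes, gene_pos) if p < 0]
        raise ValueError(f"unknown genes: {missing[:5]}")
    if n_pcs > min(em.n_cells, len(gene_pos)):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells, genes) = "
            f"{min(em.n_cells, len(gene_pos))}"
        )
    x = em.dense(genes=gene_pos)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(n_pcs):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    return u[:, :n_pcs] * s[:n_pcs]
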