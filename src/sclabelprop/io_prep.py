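"""Count-matrix I/O, quality filtering, log-normalization and PCA embedding.

The preprocessing recipe is the standard scRNA-seq one: drop cells that
express fewer than 200 genes, then drop genes expressed in fewer than 3 of
the surviving cells, rescale each cell to 10,000 counts and take ``log1p``
(natural log), and finally project to at most 500 principal components.
The fitted PCA map (components + gene means) is kept on the embedding so
that downstream gene-level attribution can chain multipliers through it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "RawCountMatrix",
    "NormalizedMatrix",
    "PCAEmbedding",
    "read_counts",
    "filter_counts",
    "lognormalize",
    "pca_project",
]


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        raise ValueError(f"{what} must be unique")


@dataclass
class RawCountMatrix:
    """Cells-by-genes matrix of non-negative integer UMI/read counts."""

    counts: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length does not match counts columns")
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length does not match counts rows")
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_ids, "cell ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``log1p(10_000 * x / rowsum)`` per cell."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PCAEmbedding:
    """PCA coordinates plus the fitted linear map.

    ``coords == (values - gene_means) @ components.T``; the components and
    gene means are retained so gene-space attributions can be recovered from
    PC-space multipliers.
    """

    coords: np.ndarray
    components: np.ndarray  # (d, n_genes)
    gene_means: np.ndarray  # (n_genes,)
    d: int

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _read_sidecar(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    # 10x-style gene sidecars carry (id, symbol); use the last column.
    return df.iloc[:, -1].tolist()


def _read_mtx_triplet(path: Path) -> RawCountMatrix:
    if path.is_dir():
        matrix_path = path / "matrix.mtx"
    else:
        matrix_path = path
    base = matrix_path.parent
    genes_path = base / "genes.tsv"
    barcodes_path = base / "barcodes.tsv"
    for p in (matrix_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"mtx triplet member missing: {p}")
    try:
        mat = np.asarray(mmread(str(matrix_path)).todense())
    except Exception as exc:  # scipy raises ValueError with line context
        raise ValueError(f"failed to parse {matrix_path}: {exc}") from exc
    genes = _read_sidecar(genes_path)
    barcodes = _read_sidecar(barcodes_path)
    r, c = mat.shape
    # Orientation auto-detect; square matrices default to the 10x
    # genes-as-rows convention.
    if r == len(genes) and c == len(barcodes):
        mat = mat.T
    elif r == len(barcodes) and c == len(genes):
        pass
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (genes={len(genes)}, "
            f"barcodes={len(barcodes)}) orientation"
        )
    return RawCountMatrix(mat, genes, barcodes)


def _read_csv_counts(path: Path) -> RawCountMatrix:
    try:
        df = pd.read_csv(path, index_col=0, sep=None, engine="python")
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    return RawCountMatrix(
        df.to_numpy(), [str(g) for g in df.columns], [str(i) for i in df.index]
    )


def read_counts(path: str | Path, format: str = "csv") -> RawCountMatrix:
    """Read a count matrix from disk, returned in cells-as-rows orientation.

    Parameters
    ----------
    path
        For ``format="mtx_triplet"``, either the ``matrix.mtx`` file or the
        directory holding ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``.
        For ``format="csv"``, a dense cells x genes table with a header row
        of gene names and a first column of cell ids.
    format
        ``"mtx_triplet"`` (alias ``"mtx"``) or ``"csv"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("mtx_triplet", "mtx"):
        return _read_mtx_triplet(path)
    if format in ("csv", "tsv"):
        return _read_csv_counts(path)
    raise ValueError(f"unknown counts format: {format!r}")


def filter_counts(
    X: RawCountMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
) -> tuple[RawCountMatrix, np.ndarray, np.ndarray]:
    """Sequential quality filter: cells first, then genes.

    Cells expressing fewer than ``min_genes_per_cell`` genes (count > 0) are
    removed first; genes expressed in fewer than ``min_cells_per_gene`` of
    the *surviving* cells are then removed. Returns the filtered matrix plus
    the retained cell and gene indices into the input, so externally supplied
    per-cell tables can be subset consistently.
    """
    expressed = X.counts > 0
    cell_keep = np.flatnonzero(expressed.sum(axis=1) >= min_genes_per_cell)
    if cell_keep.size == 0:
        raise ValueError(
            "all cells removed by the min-genes filter; lower "
            "min_genes_per_cell for this dataset"
        )
    gene_keep = np.flatnonzero(
        expressed[cell_keep].sum(axis=0) >= min_cells_per_gene
    )
    if gene_keep.size == 0:
        raise ValueError(
            "all genes removed by the min-cells filter; lower "
            "min_cells_per_gene for this dataset"
        )
    out = RawCountMatrix(
        X.counts[np.ix_(cell_keep, gene_keep)],
        [X.gene_names[j] for j in gene_keep],
        [X.cell_ids[i] for i in cell_keep],
    )
    return out, cell_keep, gene_keep


def lognormalize(X: RawCountMatrix, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize each cell to ``target_sum`` and take ``log1p``.

    ``x_i = log(1 + target_sum * x_i / sum_j(x_ij))`` with the natural log;
    zero counts stay exactly zero.
    """
    row_sums = X.counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError(
            "cells with zero total counts present; run filter_counts first"
        )
    values = np.log1p(X.counts * (target_sum / row_sums[:, None]))
    return NormalizedMatrix(values, list(X.gene_names), list(X.cell_ids))


def pca_project(X: NormalizedMatrix, d: int = 500, seed: int = 0) -> PCAEmbedding:
    """Mean-centered PCA of the normalized matrix down to ``d`` components.

    The effective dimensionality is ``min(d, n_cells, n_genes)``; gene
    variances are not rescaled (centering only).
    """
    if d < 1:
        raise ValueError("d must be a positive integer")
    if X.n_cells == 0 or X.n_genes == 0:
        raise ValueError("cannot run PCA on an empty matrix")
    d_eff = min(d, X.n_cells, X.n_genes)
    if d_eff < d:
        logger.info("PCA dimension truncated from %d to %d", d, d_eff)
    pca = PCA(n_components=d_eff, svd_solver="auto", random_state=seed)
    coords = pca.fit_transform(X.values)
    return PCAEmbedding(
        coords=np.asarray(coords, dtype=np.float64),
        components=np.asarray(pca.components_, dtype=np.float64),
        gene_means=np.asarray(pca.mean_, dtype=np.float64),
        d=d_eff,
    )
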