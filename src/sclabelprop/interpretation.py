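"""DeepLIFT (Rescale rule) attribution of the trained network back to genes.

Attribution explains the difference between each cell's predicted class
score and the score a neutral reference input would receive. The reference
is the all-zero matrix in normalized gene-expression space, pushed through
the same frozen pipeline as the data: centering by the PCA gene means, the
PCA linear map, and the very k-NN graphs recorded from the actual input's
forward pass (graph construction is discrete structure and is not
attributed).

Multipliers are propagated backward with the Rescale rule: affine
operations use their weights, and each elementwise nonlinearity with input
delta ``dx = x - x0`` uses ``(f(x) - f(x0)) / dx``, falling back to the
analytic derivative when ``|dx| < 1e-7``. Because the PCA map is linear,
gene-space multipliers are the PC-space multipliers times the component
matrix, and the attribution of gene g in cell i is ``multiplier * x[i, g]``
(the reference expression being zero). Summation-to-delta holds per batch:
the attributions over all cells and genes sum to the total score delta of
the targeted outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gcn import _ACTIVATIONS, GCNModel, _forward_cached, _make_batches
from .io_prep import NormalizedMatrix, PCAEmbedding

logger = logging.getLogger(__name__)

#: Below this input delta the Rescale ratio falls back to the derivative.
RESCALE_EPS = 1e-7

__all__ = [
    "AttributionMatrix",
    "ImportanceTable",
    "deeplift_attribute",
    "aggregate_importance",
    "top_genes",
    "augment_markers",
]


@dataclass
class AttributionMatrix:
    """Signed per-cell, per-gene contributions to each cell's target score."""

    scores: np.ndarray  # (n_cells, n_genes)
    target_class: np.ndarray  # (n_cells,)
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution scores must be finite")


@dataclass
class ImportanceTable:
    """Per-cell-type gene importance: mean attribution -> abs -> unit variance."""

    importance: np.ndarray  # (C_present, n_genes)
    cell_types: list[str]
    gene_names: list[str]
    degenerate: list[str] = field(default_factory=list)


def _rescale_multiplier(Z, Z0, activation: str) -> np.ndarray:
    act, act_grad = _ACTIVATIONS[activation]
    dZ = Z - Z0
    small = np.abs(dZ) < RESCALE_EPS
    safe = np.where(small, 1.0, dZ)
    ratio = (act(Z) - act(Z0)) / safe
    return np.where(small, act_grad(Z), ratio)


def deeplift_attribute(
    model: GCNModel,
    embedding: PCAEmbedding,
    X: NormalizedMatrix,
    targets: np.ndarray,
    inference_batch: int | None = None,
) -> AttributionMatrix:
    """Gene-level DeepLIFT-Rescale attributions for each cell's target class.

    ``targets`` is the per-cell predicted class (the output neuron whose
    score delta is explained). Cells are processed in the same deterministic
    batches as prediction; within a batch, messages flowing along graph
    edges attribute part of a cell's score to its neighbors' genes, so the
    per-cell row of the result reflects that cell's genes' contributions to
    every in-batch target that consumed them.
    """
    targets = np.asarray(targets, dtype=np.int64)
    n = embedding.coords.shape[0]
    if X.values.shape[0] != n or targets.size != n:
        raise ValueError("embedding, expression matrix and targets must align")
    if model.in_dim != embedding.coords.shape[1]:
        raise ValueError("model input width does not match embedding dimension")
    if np.any(targets < 0) or np.any(targets >= model.n_classes):
        raise ValueError("targets must be valid class indices")
    if inference_batch is None:
        inference_batch = n if n <= 5000 else 1000

    # Reference: zero expression, same frozen preprocessing.
    ref_pc = (0.0 - embedding.gene_means) @ embedding.components.T  # (d,)
    A = np.empty((n, X.values.shape[1]))
    for batch in _make_batches(
        np.arange(n), inference_batch, model.config.n_neighbors
    ):
        P = embedding.coords[batch]
        scores, H_last, caches, graphs = _forward_cached(model, P)
        P0 = np.broadcast_to(ref_pc, P.shape)
        scores0, H0_last, caches0, _ = _forward_cached(model, P0, graphs=graphs)

        m = batch.size
        M_out = np.zeros((m, model.n_classes))
        M_out[np.arange(m), targets[batch]] = 1.0
        M_H = M_out @ model.out_weight
        for layer, cache, cache0 in zip(
            reversed(model.layers), reversed(caches), reversed(caches0)
        ):
            graph = cache["graph"]
            tgt, src = graph.targets, graph.sources
            M_S = M_H[tgt]
            M_Z = M_S * _rescale_multiplier(
                cache["Z"], cache0["Z"], model.config.activation
            )
            M_pair = M_Z @ layer.theta
            f_in = layer.f_in
            ma, mb = M_pair[:, :f_in], M_pair[:, f_in:]
            M_H_in = (ma - mb).reshape(m, graph.degree, f_in).sum(axis=1)
            np.add.at(M_H_in, src, mb)
            M_H = M_H_in
        # Chain through the (linear) PCA map; reference expression is zero.
        A[batch] = (M_H @ embedding.components) * X.values[batch]
    return AttributionMatrix(A, targets.copy(), list(X.gene_names))


def aggregate_importance(
    A: AttributionMatrix, labels: np.ndarray, cell_types: list[str]
) -> ImportanceTable:
    """Collapse attributions into one importance row per cell type.

    Per type: mean attribution over that type's cells, then elementwise
    absolute value, then division of the row by its standard deviation so
    importances are comparable across types. Rows whose sd is zero are left
    unscaled and flagged degenerate; types with no cells are omitted.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size != A.scores.shape[0]:
        raise ValueError("labels must align with attribution rows")
    rows, present, degenerate = [], [], []
    for idx, name in enumerate(cell_types):
        mask = labels == idx
        if not mask.any():
            logger.info("cell type %s has no cells; importance row omitted", name)
            continue
        row = np.abs(A.scores[mask].mean(axis=0))
        sd = row.std(ddof=0)
        if sd == 0.0:
            degenerate.append(name)
        else:
            row = row / sd
        rows.append(row)
        present.append(name)
    return ImportanceTable(
        np.asarray(rows), present, list(A.gene_names), degenerate
    )


def top_genes(imp: ImportanceTable, n: int) -> dict[str, list[str]]:
    """Top-``n`` genes per type by descending importance, ties alphabetical."""
    if n < 1:
        raise ValueError("n must be at least 1")
    names = np.asarray(imp.gene_names)
    out: dict[str, list[str]] = {}
    for row, cell_type in zip(imp.importance, imp.cell_types):
        order = np.lexsort((names, -row))
        out[cell_type] = names[order][:n].tolist()
    return out


def augment_markers(
    markers: dict[str, list[str]],
    imp: ImportanceTable,
    n_add: int = 3,
) -> dict[str, list[str]]:
    """Append the top ``n_add`` attributed genes not already in a type's list.

    Original markers are preserved in order and come first; the importance
    ranking is walked from the top and the first ``n_add`` genes absent from
    that type's existing marker list are appended. Types without an
    importance row are returned unchanged.
    """
    ranking = top_genes(imp, len(imp.gene_names)) if n_add > 0 else {}
    vocab = set(imp.gene_names)
    out: dict[str, list[str]] = {}
    for cell_type, genes in markers.items():
        missing = [g for g in genes if g not in vocab]
        if missing:
            raise ValueError(
                f"markers for {cell_type} not in gene vocabulary: {missing}"
            )
        augmented = list(genes)
        if n_add > 0 and cell_type in ranking:
            existing = set(genes)
            novel = [g for g in ranking[cell_type] if g not in existing][:n_add]
            if len(novel) < n_add:
                logger.warning(
                    "only %d novel genes available for %s", len(novel), cell_type
                )
            augmented.extend(novel)
        out[cell_type] = augmented
    return out
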