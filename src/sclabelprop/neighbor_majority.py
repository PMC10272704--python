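"""Nonparametric neighbor-majority label propagation baseline.

Starting from the consensus labels, each unconfident cell repeatedly takes
the majority label of its k nearest neighbors in PC space, counting only
neighbors that are already labeled. Updates are synchronous within an epoch
(every cell sees the previous epoch's labels) and confident cells never
change. Three stopping strategies are supported: a single round, iteration
until fewer than 5% of labels change between epochs, and iteration until all
cells are labeled or 50 epochs have passed.

Unlike the GCN's per-batch dynamic graphs, the k-NN structure here is fixed:
geometry never changes during propagation, only labels do.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .consensus import ConsensusLabels
from .gcn import evaluate_accuracy
from .graph import build_knn_graph
from .io_prep import PCAEmbedding

logger = logging.getLogger(__name__)

#: Sentinel for a cell that is still unlabeled (same encoding as consensus -1).
UNLABELED = -1

#: Returned by :func:`majority_of` on ties or when no neighbor is labeled.
NO_WINNER = -1

STRATEGIES = ("one_round", "low_change", "until_labeled")

__all__ = [
    "UNLABELED",
    "NO_WINNER",
    "STRATEGIES",
    "PropagationResult",
    "majority_of",
    "propagate_neighbor_majority",
    "select_neighbor_params",
]


@dataclass
class PropagationResult:
    labels: np.ndarray
    epochs: int
    changed_history: list[float]


def majority_of(neighbor_labels: np.ndarray) -> int:
    """Strict plurality among the labeled entries; ties or no labeled
    neighbors give NO_WINNER."""
    labs = np.asarray(neighbor_labels)
    labs = labs[labs >= 0]
    if labs.size == 0:
        return NO_WINNER
    vals, counts = np.unique(labs, return_counts=True)
    top = counts.max()
    if (counts == top).sum() > 1:
        return NO_WINNER
    return int(vals[counts.argmax()])


def _batch_indices(n: int, batch_size: int, k: int, rng: np.random.Generator):
    order = rng.permutation(n)
    batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and batches[-1].size < k + 1:
        logger.info("merging trailing batch of %d cells", batches[-1].size)
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _majority_rows(nb_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Vectorized strict-plurality vote per row; NO_WINNER on ties/empties."""
    counts = np.zeros((nb_labels.shape[0], n_classes), dtype=np.int64)
    for cls in range(n_classes):
        counts[:, cls] = (nb_labels == cls).sum(axis=1)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    out = np.where((top == 0) | tied, NO_WINNER, counts.argmax(axis=1))
    return out.astype(np.int64)


def propagate_neighbor_majority(
    embedding: PCAEmbedding,
    c: ConsensusLabels | np.ndarray,
    k: int,
    strategy: str = "until_labeled",
    batch_size: int = 1000,
    seed: int = 0,
    max_epochs: int = 50,
    change_tol: float = 0.05,
    n_classes: int | None = None,
) -> PropagationResult:
    """Propagate confident labels to unconfident cells by k-NN majority vote.

    Cells are partitioned once into seeded batches of at most ``batch_size``;
    a k-NN graph (k nearest *other* cells, Euclidean distance on the PC
    coordinates) is built per batch and reused across epochs. Cells still
    unlabeled when the strategy stops remain at ``UNLABELED``.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    labels = (
        c.labels.copy() if isinstance(c, ConsensusLabels) else np.asarray(c).copy()
    )
    n = labels.size
    if embedding.coords.shape[0] != n:
        raise ValueError("embedding rows do not match label vector")
    if n_classes is None:
        if isinstance(c, ConsensusLabels) and c.cell_types:
            n_classes = len(c.cell_types)
        else:
            n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    batches = _batch_indices(n, batch_size, k, rng)
    neighbor_sets = [
        (batch, batch[build_knn_graph(embedding.coords[batch], k, include_self=False).neighbors])
        for batch in batches
    ]

    changed_history: list[float] = []
    epoch = 0
    while True:
        epoch += 1
        new_labels = labels.copy()
        for batch, nbrs in neighbor_sets:
            unl_local = np.flatnonzero(labels[batch] == UNLABELED)
            if unl_local.size == 0:
                continue
            votes = _majority_rows(labels[nbrs[unl_local]], n_classes)
            winners = votes != NO_WINNER
            new_labels[batch[unl_local[winners]]] = votes[winners]
        changed = float(np.mean(new_labels != labels))
        changed_history.append(changed)
        labels = new_labels
        if strategy == "one_round":
            break
        if strategy == "low_change" and (changed < change_tol or epoch >= max_epochs):
            break
        if strategy == "until_labeled" and (
            not np.any(labels == UNLABELED) or epoch >= max_epochs
        ):
            break
    return PropagationResult(labels, epoch, changed_history)


def select_neighbor_params(
    embedding: PCAEmbedding,
    c: ConsensusLabels,
    val_mask: np.ndarray,
    ks: tuple[int, ...] = (2, 5, 10, 25, 50),
    strategies: tuple[str, ...] = STRATEGIES,
    batch_size: int = 1000,
    seed: int = 0,
) -> tuple[int, str, list[dict]]:
    """Choose k and the stopping strategy on the validation mask.

    Validation cells are hidden (set to unlabeled) before propagation; each
    (k, strategy) pair is then scored by accuracy against the consensus
    labels on those cells, with cells left unlabeled counting as incorrect.
    Ties go to the earlier (k, strategy) pair in sweep order.
    """
    val_mask = np.asarray(val_mask, dtype=bool)
    if not val_mask.any():
        raise ValueError("validation mask is empty")
    masked = c.labels.copy()
    masked[val_mask] = UNLABELED
    masked_c = ConsensusLabels(masked, c.threshold, list(c.cell_types))
    results = []
    best = (ks[0], strategies[0], -1.0)
    for k, strategy in itertools.product(ks, strategies):
        if k >= min(batch_size, embedding.n_cells):
            continue
        res = propagate_neighbor_majority(
            embedding, masked_c, k, strategy, batch_size=batch_size, seed=seed
        )
        acc = evaluate_accuracy(res.labels, c.labels, val_mask)
        results.append({"k": k, "strategy": strategy, "val_accuracy": acc})
        if acc > best[2]:
            best = (k, strategy, acc)
    return best[0], best[1], results
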