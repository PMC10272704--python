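"""Consensus voting over an ensemble of cell-type annotation tools.

Each of ``t`` external tools assigns every cell a categorical label or
abstains. Votes are tallied per cell; a cell is *confidently* labeled when
the plurality type holds at least a 0.51 fraction of the votes actually cast
(a simple majority), and is marked ``-1`` (unconfident) otherwise. The
*max consensus* baseline instead takes the strict plurality and returns
"unknown" on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel used inside prediction tables for a tool that abstained.
ABSTAIN = "<abstain>"

#: Integer sentinel returned by :func:`max_consensus` for tied cells.
UNKNOWN = -2

#: Strings (lower-cased) parsed as abstentions in prediction CSVs.
_ABSTAIN_ALIASES = {"", "na", "nan", "none", "unknown", "unassigned"}

__all__ = [
    "ABSTAIN",
    "UNKNOWN",
    "PredictionTable",
    "VoteMatrix",
    "ConsensusLabels",
    "read_predictions",
    "infer_cell_types",
    "encode_votes",
    "confident_labels",
    "max_consensus",
    "consensus_summary",
]


@dataclass
class PredictionTable:
    """n x t categorical predictions, one column per annotation tool."""

    preds: np.ndarray  # object dtype, entries are labels or ABSTAIN
    tool_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.preds = np.asarray(self.preds, dtype=object)
        if self.preds.ndim != 2:
            raise ValueError("preds must be a 2-D cells x tools array")
        if self.preds.shape != (len(self.cell_ids), len(self.tool_names)):
            raise ValueError("preds shape does not match cell_ids/tool_names")

    @property
    def n_cells(self) -> int:
        return self.preds.shape[0]

    @property
    def n_tools(self) -> int:
        return self.preds.shape[1]

    def subset_cells(self, indices: np.ndarray) -> "PredictionTable":
        return PredictionTable(
            self.preds[indices],
            list(self.tool_names),
            [self.cell_ids[i] for i in indices],
        )


@dataclass
class VoteMatrix:
    """n x C vote tallies over an ordered cell-type vocabulary."""

    votes: np.ndarray
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes)
        if np.any(self.votes < 0) or not np.issubdtype(self.votes.dtype, np.integer):
            raise ValueError("votes must be non-negative integers")


@dataclass
class ConsensusLabels:
    """Per-cell confident label index, or -1 where no majority was reached."""

    labels: np.ndarray
    threshold: float
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0.5, 1]")

    @property
    def confident_mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def n_confident(self) -> int:
        return int(np.count_nonzero(self.labels >= 0))


def _normalize_entry(value: object) -> str:
    s = str(value).strip()
    if s.lower() in _ABSTAIN_ALIASES:
        return ABSTAIN
    return s


def read_predictions(path: str | Path) -> PredictionTable:
    """Read a prediction CSV: first column cell ids, one column per tool.

    Empty strings, "NA", "NaN", "none", "unknown" and "unassigned"
    (case-insensitive) are parsed as abstentions.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    preds = np.vectorize(_normalize_entry, otypes=[object])(df.to_numpy(dtype=object))
    return PredictionTable(preds, [str(t) for t in df.columns], [str(i) for i in df.index])


def infer_cell_types(R: PredictionTable) -> list[str]:
    """Lexicographically sorted vocabulary of all non-abstain labels."""
    labels = {str(v) for v in R.preds.ravel() if v != ABSTAIN}
    return sorted(labels)


def encode_votes(R: PredictionTable, cell_types: list[str]) -> VoteMatrix:
    """Tally tool votes per cell over the given vocabulary.

    ``votes[i, c]`` is the number of tools predicting type ``c`` for cell
    ``i``; abstentions contribute nothing. Labels outside the vocabulary
    raise a ``ValueError`` naming the offenders.
    """
    index = {t: j for j, t in enumerate(cell_types)}
    unseen = sorted(
        {str(v) for v in R.preds.ravel() if v != ABSTAIN and str(v) not in index}
    )
    if unseen:
        raise ValueError(f"predictions contain labels outside the vocabulary: {unseen}")
    votes = np.zeros((R.n_cells, len(cell_types)), dtype=np.int64)
    for j in range(R.n_tools):
        col = R.preds[:, j]
        for i, v in enumerate(col):
            if v != ABSTAIN:
                votes[i, index[str(v)]] += 1
    return VoteMatrix(votes, list(cell_types))


def confident_labels(
    E: VoteMatrix,
    threshold: float = 0.51,
    *,
    denominator: str = "cast",
    n_tools: int | None = None,
) -> ConsensusLabels:
    """Assign each cell its majority label, or -1 if no majority.

    For cell ``i`` the confidence is ``m_i = max(E_i) / sum(E_i)`` (votes
    actually cast); the cell receives the argmax type when
    ``m_i >= threshold`` and -1 otherwise. Cells with zero cast votes are
    unconfident. With ``denominator="tools"`` the stricter variant dividing
    by the total tool count ``n_tools`` is used instead.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    votes = E.votes
    cast = votes.sum(axis=1)
    if denominator == "cast":
        denom = cast.astype(float)
    elif denominator == "tools":
        if n_tools is None:
            raise ValueError('denominator="tools" requires n_tools')
        denom = np.full(votes.shape[0], float(n_tools))
    else:
        raise ValueError(f"unknown denominator rule: {denominator!r}")
    top = votes.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, top / denom, 0.0)
    labels = np.where((m >= threshold) & (cast > 0), votes.argmax(axis=1), -1)
    return ConsensusLabels(labels, threshold, list(E.cell_types))


def max_consensus(E: VoteMatrix) -> np.ndarray:
    """Strict plurality label per cell; ties (and zero rows) give UNKNOWN."""
    votes = E.votes
    top = votes.max(axis=1)
    tied = (votes == top[:, None]).sum(axis=1) > 1
    labels = np.where(tied | (top == 0), UNKNOWN, votes.argmax(axis=1))
    return labels.astype(np.int64)


def consensus_summary(c: ConsensusLabels) -> dict:
    """Counts of confident/unconfident cells and per-type tallies."""
    confident = int(np.count_nonzero(c.labels >= 0))
    per_type = {
        name: int(np.count_nonzero(c.labels == idx))
        for idx, name in enumerate(c.cell_types)
    }
    return {
        "n_cells": int(c.labels.size),
        "n_confident": confident,
        "n_unconfident": int(c.labels.size - confident),
        "per_type": per_type,
    }
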