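"""k-nearest-neighbor graphs over cell feature vectors.

Graphs are stored as a constant-degree neighbor table: row ``i`` lists the
source nodes whose features flow into node ``i`` (the self-loop first when
present, then the k nearest other nodes in Euclidean distance). Exact
distance ties are broken toward the lower node index so graph construction
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KNNGraph", "build_knn_graph"]


@dataclass
class KNNGraph:
    neighbors: np.ndarray  # (m, degree) source node per target row
    k: int
    include_self: bool

    @property
    def n_nodes(self) -> int:
        return self.neighbors.shape[0]

    @property
    def degree(self) -> int:
        return self.neighbors.shape[1]

    @property
    def targets(self) -> np.ndarray:
        """Edge target indices, one per (node, neighbor) pair."""
        return np.repeat(np.arange(self.n_nodes), self.degree)

    @property
    def sources(self) -> np.ndarray:
        """Edge source indices aligned with :attr:`targets`."""
        return self.neighbors.ravel()

    def edge_set(self) -> set[tuple[int, int]]:
        return set(zip(self.targets.tolist(), self.sources.tolist()))


def build_knn_graph(
    features: np.ndarray, k: int, include_self: bool = True
) -> KNNGraph:
    """k-NN graph in Euclidean distance, with optional self-loops.

    Each node receives edges from its ``k`` nearest *other* nodes plus, when
    ``include_self``, a self-loop (listed first). Requires more nodes than
    neighbors (``m > k``).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features[:, None]
    m = features.shape[0]
    if m <= k:
        raise ValueError(f"need more than k={k} nodes to build a k-NN graph, got {m}")
    if k == 0:
        nn = np.empty((m, 0), dtype=np.int64)
    else:
        d2 = cdist(features, features, metric="sqeuclidean")
        np.fill_diagonal(d2, np.inf)
        # stable sort => distance ties resolved toward the lower index
        nn = np.argsort(d2, axis=1, kind="stable")[:, :k].astype(np.int64)
    if include_self:
        self_col = np.arange(m, dtype=np.int64)[:, None]
        nn = np.concatenate([self_col, nn], axis=1)
    return KNNGraph(nn, k=k, include_self=include_self)
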