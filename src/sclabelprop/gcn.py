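"""Semi-supervised EdgeConv graph network for label propagation.

The model is a small dynamic-graph network in the DGCNN style: each EdgeConv
layer builds a k-nearest-neighbor graph on its *input* features (the PCA
coordinates at the first layer), computes a message
``SiLU(theta @ concat(x_i, x_j - x_i) + bias)`` per edge and sums messages
into each target node; a final linear layer maps the node embedding to
class scores. Training minimizes cross-entropy on the confidently labeled
cells only, over freshly shuffled minibatches each epoch, with Adam.
Unconfident cells still participate in every forward pass — they shape the
graphs — but never contribute to the loss.

Everything is plain NumPy with hand-written backpropagation, which keeps the
model CPU-only, dependency-light, and transparent to the attribution code in
:mod:`sclabelprop.interpretation`.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .consensus import ConsensusLabels
from .graph import KNNGraph, build_knn_graph
from .io_prep import PCAEmbedding

logger = logging.getLogger(__name__)

__all__ = [
    "GCNConfig",
    "EdgeConvLayer",
    "GCNModel",
    "TrainingLog",
    "silu",
    "silu_grad",
    "edgeconv_forward",
    "gcn_forward",
    "split_validation",
    "train_gcn",
    "predict_labels",
    "grid_search",
    "default_grid",
    "evaluate_accuracy",
    "multi_seed_report",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(x: np.ndarray) -> np.ndarray:
    """SiLU activation, ``x * sigmoid(x)``."""
    return x * _sigmoid(x)


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


_ACTIVATIONS = {
    "silu": (silu, silu_grad),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class GCNConfig:
    """Hyperparameters of the propagation network.

    ``batch_size`` must exceed ``n_neighbors`` so every minibatch can host a
    k-NN graph; ``embed_dim`` should be at least the number of classes.
    """

    batch_size: int = 20
    n_neighbors: int = 2
    n_layers: int = 2
    embed_dim: int = 25
    learning_rate: float = 1e-4
    epochs: int = 150
    seed: int = 0
    activation: str = "silu"
    dynamic_graph: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < self.n_neighbors + 1:
            raise ValueError("batch_size must be at least n_neighbors + 1")
        if self.n_layers < 1:
            raise ValueError("need at least one EdgeConv layer")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class EdgeConvLayer:
    """One EdgeConv block: affine map on (x_i, x_j - x_i) pair features."""

    theta: np.ndarray  # (f_out, 2 * f_in)
    bias: np.ndarray  # (f_out,)

    @property
    def f_in(self) -> int:
        return self.theta.shape[1] // 2

    @property
    def f_out(self) -> int:
        return self.theta.shape[0]


@dataclass
class GCNModel:
    layers: list[EdgeConvLayer]
    out_weight: np.ndarray  # (C, e)
    out_bias: np.ndarray  # (C,)
    config: GCNConfig
    in_dim: int
    n_classes: int

    @classmethod
    def initialize(
        cls, in_dim: int, n_classes: int, config: GCNConfig, rng: np.random.Generator
    ) -> "GCNModel":
        """Seeded uniform Kaiming-style (fan-in) initialization."""
        if config.embed_dim < n_classes:
            raise ValueError("embed_dim must be at least the number of classes")
        widths = [in_dim] + [config.embed_dim] * config.n_layers
        layers = []
        for f_in, f_out in zip(widths[:-1], widths[1:]):
            bound = 1.0 / np.sqrt(2 * f_in)
            layers.append(
                EdgeConvLayer(
                    theta=rng.uniform(-bound, bound, size=(f_out, 2 * f_in)),
                    bias=rng.uniform(-bound, bound, size=f_out),
                )
            )
        bound = 1.0 / np.sqrt(config.embed_dim)
        return cls(
            layers=layers,
            out_weight=rng.uniform(-bound, bound, size=(n_classes, config.embed_dim)),
            out_bias=rng.uniform(-bound, bound, size=n_classes),
            config=config,
            in_dim=in_dim,
            n_classes=n_classes,
        )

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.theta, layer.bias])
        out.extend([self.out_weight, self.out_bias])
        return out

    def save(self, path: str | Path) -> None:
        arrays = {"out_weight": self.out_weight, "out_bias": self.out_bias}
        for i, layer in enumerate(self.layers):
            arrays[f"theta_{i}"] = layer.theta
            arrays[f"bias_{i}"] = layer.bias
        meta = dict(vars(self.config))
        np.savez(
            path,
            **arrays,
            _meta=np.array(
                [repr({**meta, "in_dim": self.in_dim, "n_classes": self.n_classes})],
                dtype=object,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GCNModel":
        with np.load(path, allow_pickle=True) as data:
            meta = eval(data["_meta"][0])  # noqa: S307 - own checkpoint format
            in_dim = meta.pop("in_dim")
            n_classes = meta.pop("n_classes")
            config = GCNConfig(**meta)
            layers = []
            for i in range(config.n_layers):
                layers.append(EdgeConvLayer(data[f"theta_{i}"], data[f"bias_{i}"]))
            return cls(
                layers, data["out_weight"], data["out_bias"], config, in_dim, n_classes
            )


def edgeconv_forward(
    features: np.ndarray,
    graph: KNNGraph,
    layer: EdgeConvLayer,
    activation: str = "silu",
) -> np.ndarray:
    """One EdgeConv layer: ``out_i = sum_{j in N(i)} act(theta @ (x_i, x_j - x_i) + b)``.

    The self-loop contributes the pair feature ``(x_i, 0)``.
    """
    out, _ = _edgeconv_forward_cached(features, graph, layer, activation)
    return out


def _edgeconv_forward_cached(features, graph, layer, activation):
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != graph.n_nodes:
        raise ValueError("feature rows do not match graph nodes")
    if features.shape[1] != layer.f_in:
        raise ValueError(
            f"feature width {features.shape[1]} does not match layer f_in {layer.f_in}"
        )
    act, _ = _ACTIVATIONS[activation]
    tgt, src = graph.targets, graph.sources
    pair = np.concatenate(
        [features[tgt], features[src] - features[tgt]], axis=1
    )  # (E, 2 f_in)
    Z = pair @ layer.theta.T + layer.bias
    S = act(Z)
    out = S.reshape(graph.n_nodes, graph.degree, layer.f_out).sum(axis=1)
    cache = {"H_in": features, "graph": graph, "pair": pair, "Z": Z}
    return out, cache


def _forward_cached(
    model: GCNModel,
    features: np.ndarray,
    k: int | None = None,
    graphs: Sequence[KNNGraph] | None = None,
):
    """Full forward pass; returns scores, per-layer caches and the graphs used."""
    k = model.config.n_neighbors if k is None else k
    H = np.asarray(features, dtype=np.float64)
    caches: list[dict] = []
    used_graphs: list[KNNGraph] = []
    static_graph: KNNGraph | None = None
    for i, layer in enumerate(model.layers):
        if graphs is not None:
            graph = graphs[i]
        elif model.config.dynamic_graph or static_graph is None:
            graph = build_knn_graph(H, k)
            static_graph = graph
        else:
            graph = static_graph
        H, cache = _edgeconv_forward_cached(H, graph, layer, model.config.activation)
        caches.append(cache)
        used_graphs.append(graph)
    scores = H @ model.out_weight.T + model.out_bias
    return scores, H, caches, used_graphs


def gcn_forward(
    model: GCNModel,
    features: np.ndarray,
    k: int | None = None,
    graphs: Sequence[KNNGraph] | None = None,
) -> np.ndarray:
    """Class scores for every node.

    The first EdgeConv layer builds its k-NN graph on the input (PCA)
    features; each subsequent layer rebuilds it dynamically on its own input
    features unless the model was configured with ``dynamic_graph=False`` or
    explicit ``graphs`` are supplied.
    """
    scores, _, _, _ = _forward_cached(model, features, k=k, graphs=graphs)
    return scores


def _backward(model: GCNModel, caches, H_last, dscores):
    """Gradients of a scalar loss w.r.t. all parameters, given dL/dscores."""
    _, act_grad = _ACTIVATIONS[model.config.activation]
    grads: list[np.ndarray] = []
    d_out_w = dscores.T @ H_last
    d_out_b = dscores.sum(axis=0)
    dH = dscores @ model.out_weight
    for layer, cache in zip(reversed(model.layers), reversed(caches)):
        graph: KNNGraph = cache["graph"]
        tgt, src = graph.targets, graph.sources
        dS = dH[tgt]
        dZ = dS * act_grad(cache["Z"])
        d_theta = dZ.T @ cache["pair"]
        d_bias = dZ.sum(axis=0)
        dpair = dZ @ layer.theta  # (E, 2 f_in)
        f_in = layer.f_in
        da, db = dpair[:, :f_in], dpair[:, f_in:]
        dH_in = (da - db).reshape(graph.n_nodes, graph.degree, f_in).sum(axis=1)
        np.add.at(dH_in, src, db)
        grads.append(d_bias)
        grads.append(d_theta)
        dH = dH_in
    grads.reverse()
    grads.extend([d_out_w, d_out_b])
    return grads, dH


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainingLog:
    """Per-epoch mean loss plus loss-participation bookkeeping.

    ``loss_cells_used[i]`` is True iff cell ``i``'s label ever entered the
    cross-entropy — by construction only confident, train-mask cells can.
    """

    losses: np.ndarray
    loss_cells_used: np.ndarray
    skipped_batches: int = 0


def _make_batches(order: np.ndarray, batch_size: int, k: int) -> list[np.ndarray]:
    """Split an index order into batches; a trailing batch of size <= k is
    merged into the previous one so every batch can host a k-NN graph."""
    n = order.size
    batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and batches[-1].size <= k:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    if batches and batches[0].size <= k:
        raise ValueError("batch smaller than k + 1; decrease n_neighbors")
    return batches


def _as_labels(c) -> np.ndarray:
    if isinstance(c, ConsensusLabels):
        return c.labels
    return np.asarray(c, dtype=np.int64)


def split_validation(
    c: ConsensusLabels | np.ndarray, fraction: float = 0.20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation masks over the *confident* cells only.

    Each consensus class contributes ``round(fraction * n_class)`` cells to
    the validation mask; classes with fewer than two confident cells stay
    whole in the train mask (with a warning). Unconfident cells belong to
    neither mask.
    """
    labels = _as_labels(c)
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    train = np.zeros(labels.size, dtype=bool)
    val = np.zeros(labels.size, dtype=bool)
    for cls in np.unique(labels[labels >= 0]):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            warnings.warn(
                f"class {cls} has fewer than 2 confident cells; kept whole in train",
                stacklevel=2,
            )
            train[idx] = True
            continue
        idx = rng.permutation(idx)
        n_val = min(int(round(fraction * idx.size)), idx.size - 1)
        val[idx[:n_val]] = True
        train[idx[n_val:]] = True
    return train, val


def train_gcn(
    embedding: PCAEmbedding,
    c: ConsensusLabels | np.ndarray,
    config: GCNConfig,
    train_mask: np.ndarray | None = None,
    n_classes: int | None = None,
) -> tuple[GCNModel, TrainingLog]:
    """Train the EdgeConv network on confidently labeled cells.

    Every epoch shuffles *all* cells (confident or not) into minibatches of
    ``config.batch_size``; cross-entropy is computed only on in-batch cells
    that are confident and inside ``train_mask`` (default: all confident
    cells), and one Adam step is taken per batch. Batches containing no
    labeled cell are skipped without a step.
    """
    labels = _as_labels(c)
    n = labels.size
    if embedding.coords.shape[0] != n:
        raise ValueError("embedding rows do not match label vector")
    if train_mask is None:
        train_mask = labels >= 0
    train_mask = np.asarray(train_mask, dtype=bool)
    if n_classes is None:
        if isinstance(c, ConsensusLabels) and c.cell_types:
            n_classes = len(c.cell_types)
        else:
            n_classes = int(labels.max()) + 1
    loss_eligible = (labels >= 0) & train_mask
    if config.epochs > 0 and not loss_eligible.any():
        raise ValueError("train mask selects no confident cells")

    rng = np.random.default_rng(config.seed)
    model = GCNModel.initialize(embedding.coords.shape[1], n_classes, config, rng)
    params = model.parameters()
    opt = _Adam(params, config.learning_rate)
    losses = np.zeros(config.epochs)
    used = np.zeros(n, dtype=bool)
    skipped = 0
    coords = embedding.coords

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for batch in _make_batches(order, config.batch_size, config.n_neighbors):
            labeled_local = np.flatnonzero(loss_eligible[batch])
            if labeled_local.size == 0:
                skipped += 1
                continue
            scores, H_last, caches, _ = _forward_cached(model, coords[batch])
            y = labels[batch[labeled_local]]
            logits = scores[labeled_local]
            logits = logits - logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            probs = expl / expl.sum(axis=1, keepdims=True)
            loss = float(
                -np.log(probs[np.arange(y.size), y] + 1e-300).mean()
            )
            dscores = np.zeros_like(scores)
            dprob = probs.copy()
            dprob[np.arange(y.size), y] -= 1.0
            dscores[labeled_local] = dprob / y.size
            grads, _ = _backward(model, caches, H_last, dscores)
            opt.step(grads)
            used[batch[labeled_local]] = True
            epoch_losses.append(loss)
        losses[epoch] = float(np.mean(epoch_losses)) if epoch_losses else np.nan
    if skipped:
        logger.info("skipped %d batches with no labeled cells", skipped)
    return model, TrainingLog(losses, used, skipped)


def predict_labels(
    model: GCNModel,
    embedding: PCAEmbedding,
    inference_batch: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label every cell with the trained model.

    Cells are scored in deterministic sequential batches (the whole dataset
    at once when it has at most 5000 cells, else batches of 1000 unless
    ``inference_batch`` overrides), using the same dynamic-kNN forward pass
    as training. Ties at the argmax go to the lower class index.
    """
    n = embedding.coords.shape[0]
    if inference_batch is None:
        inference_batch = n if n <= 5000 else 1000
    order = np.arange(n)
    labels = np.empty(n, dtype=np.int64)
    scores = np.empty((n, model.n_classes))
    for batch in _make_batches(order, inference_batch, model.config.n_neighbors):
        s = gcn_forward(model, embedding.coords[batch])
        scores[batch] = s
        labels[batch] = s.argmax(axis=1)
    return labels, scores


def evaluate_accuracy(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Fraction of masked cells whose prediction equals the truth.

    UNKNOWN / unlabeled sentinel predictions (negative values) never match a
    true class and therefore count as incorrect.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors must align")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("accuracy undefined on an empty mask")
    return float(np.mean(pred[mask] == truth[mask]))


def default_grid(
    epochs: int = 150, learning_rate: float = 1e-4, seed: int = 0
) -> list[GCNConfig]:
    """The default hyperparameter grid: b in {20, 50}, k in {2, 5, 10},
    l in {1, 2, 3}, e in {25, 40}."""
    grid = []
    for b, k, l, e in itertools.product((20, 50), (2, 5, 10), (1, 2, 3), (25, 40)):
        grid.append(
            GCNConfig(
                batch_size=b,
                n_neighbors=k,
                n_layers=l,
                embed_dim=e,
                learning_rate=learning_rate,
                epochs=epochs,
                seed=seed,
            )
        )
    return grid


def grid_search(
    embedding: PCAEmbedding,
    c: ConsensusLabels,
    grid: Sequence[GCNConfig],
    seed: int = 0,
    train_mask: np.ndarray | None = None,
    val_mask: np.ndarray | None = None,
) -> tuple[GCNConfig, list[dict]]:
    """Select hyperparameters by accuracy on held-out confident cells.

    Each config is trained once (seeded with ``seed``) on the train mask and
    scored against the consensus labels on the validation mask; the best
    validation accuracy wins, ties resolved toward the earlier grid entry.
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if train_mask is None or val_mask is None:
        train_mask, val_mask = split_validation(c, 0.20, seed)
    if not np.asarray(val_mask).any():
        raise ValueError("validation mask is empty")
    labels = _as_labels(c)
    results = []
    best_idx, best_acc = 0, -1.0
    for i, cfg in enumerate(grid):
        cfg_seeded = replace(cfg, seed=seed)
        model, _ = train_gcn(embedding, c, cfg_seeded, train_mask=train_mask)
        pred, _ = predict_labels(model, embedding)
        acc = evaluate_accuracy(pred, labels, val_mask)
        results.append({"config": cfg_seeded, "val_accuracy": acc})
        if acc > best_acc:
            best_idx, best_acc = i, acc
    return results[best_idx]["config"], results


def multi_seed_report(
    embedding: PCAEmbedding,
    c: ConsensusLabels,
    config: GCNConfig,
    truth: np.ndarray | None = None,
    n_runs: int = 5,
    base_seed: int | None = None,
) -> dict:
    """Train ``n_runs`` random initializations and report accuracy mean +- sd.

    Total accuracy is measured on all cells, unconfident accuracy on the
    cells the consensus left at -1; both against the supplied truth vector
    (synthetic-data use; with ``truth=None`` only predictions and models are
    collected). Seeds are ``base_seed + run`` so the report is bit-for-bit
    reproducible.
    """
    labels = _as_labels(c)
    if base_seed is None:
        base_seed = config.seed
    unconf = labels < 0
    total, unconf_acc, preds, models = [], [], [], []
    for run in range(n_runs):
        cfg = replace(config, seed=int(base_seed + run))
        model, _ = train_gcn(embedding, c, cfg)
        pred, _ = predict_labels(model, embedding)
        preds.append(pred)
        models.append(model)
        if truth is not None:
            total.append(evaluate_accuracy(pred, truth))
            if unconf.any():
                unconf_acc.append(evaluate_accuracy(pred, truth, unconf))
    def _stats(vals):
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            return {"mean": float("nan"), "sd": float("nan"), "values": []}
        sd = float(arr.std(ddof=0)) if arr.size > 1 else 0.0
        return {"mean": float(arr.mean()), "sd": sd, "values": arr.tolist()}

    return {
        "total": _stats(total),
        "unconfident": _stats(unconf_acc),
        "predictions": preds,
        "models": models,
        "seeds": [int(base_seed + r) for r in range(n_runs)],
    }
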