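"""DeepLIFT-Rescale identities, an independent dense-multiplier oracle, and
importance aggregation."""

import numpy as np
import pytest

import sclabelprop as slp
from sclabelprop.gcn import GCNConfig, GCNModel, _forward_cached, silu, silu_grad
from sclabelprop.interpretation import (
    AttributionMatrix,
    ImportanceTable,
    _rescale_multiplier,
)


def _toy_problem(n=10, g=20, d=6, n_classes=3, seed=0, **cfg_kw):
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(1.0, 0.5, size=(n, g)))
    norm = slp.NormalizedMatrix(
        X, [f"g{j:02d}" for j in range(g)], [f"c{i}" for i in range(n)]
    )
    emb = slp.pca_project(norm, d=d, seed=seed)
    cfg = GCNConfig(
        batch_size=max(n, 10), n_neighbors=cfg_kw.pop("n_neighbors", 2),
        n_layers=2, embed_dim=5, seed=seed, **cfg_kw,
    )
    model = GCNModel.initialize(emb.d, n_classes, cfg, rng)
    targets = rng.integers(0, n_classes, size=n)
    return model, emb, norm, targets


def _score_deltas(model, emb, targets):
    """Target-class score difference between the input and the zero-expression
    reference, pushed through the graphs frozen from the input's forward."""
    scores, _, _, graphs = _forward_cached(model, emb.coords)
    ref_pc = (0.0 - emb.gene_means) @ emb.components.T
    scores0, _, _, _ = _forward_cached(
        model, np.broadcast_to(ref_pc, emb.coords.shape), graphs=graphs
    )
    idx = np.arange(targets.size)
    return scores[idx, targets] - scores0[idx, targets]


class TestRescaleMultiplier:
    def test_silu_multiplier_closed_form_and_fallback(self):
        # zero reference: multiplier = (SiLU(x) - 0) / x = sigmoid(x)
        x = np.array([2.0, -1.5, 0.3])
        mult = _rescale_multiplier(x, np.zeros(3), "silu")
        np.testing.assert_allclose(mult, 1 / (1 + np.exp(-x)), atol=1e-12)
        # near-zero delta falls back to the derivative, 0.5 at the origin
        tiny = _rescale_multiplier(np.array([1e-9]), np.zeros(1), "silu")
        np.testing.assert_allclose(tiny, [0.5], atol=1e-8)


class TestSummationToDelta:
    def test_per_cell_identity_with_self_loops_only(self):
        model, emb, norm, targets = _toy_problem(n_neighbors=0)
        A = slp.deeplift_attribute(model, emb, norm, targets)
        deltas = _score_deltas(model, emb, targets)
        np.testing.assert_allclose(
            A.scores.sum(axis=1), deltas, rtol=1e-4, atol=1e-12
        )

    def test_batch_sum_identity_with_neighbors(self):
        model, emb, norm, targets = _toy_problem(n_neighbors=3)
        A = slp.deeplift_attribute(model, emb, norm, targets)
        np.testing.assert_allclose(
            A.scores.sum(), _score_deltas(model, emb, targets).sum(), rtol=1e-4
        )


class TestLinearPipeline:
    def test_identity_activations_reduce_to_gradient_times_input(self):
        """With the nonlinearities removed the whole pipeline is linear, so
        Rescale attributions must equal gradient x (input - reference)."""
        model, emb, norm, targets = _toy_problem(
            n=6, g=8, d=4, activation="identity"
        )
        A = slp.deeplift_attribute(model, emb, norm, targets)
        # numeric gradient of the summed target scores through frozen graphs
        _, _, _, graphs = _forward_cached(model, emb.coords)

        def f(X):
            P = (X - emb.gene_means) @ emb.components.T
            s, _, _, _ = _forward_cached(model, P, graphs=graphs)
            return s[np.arange(targets.size), targets].sum()

        eps = 1e-6
        grad = np.zeros_like(norm.values)
        for i in range(norm.n_cells):
            for j in range(norm.n_genes):
                up, down = norm.values.copy(), norm.values.copy()
                up[i, j] += eps
                down[i, j] -= eps
                grad[i, j] = (f(up) - f(down)) / (2 * eps)
        np.testing.assert_allclose(A.scores, grad * norm.values, atol=1e-6)


def _dense_deeplift(model, emb, X, targets):
    """Independent Rescale implementation with explicit multiplier matrices.

    Each layer's multipliers are materialized as a dense matrix over the
    flattened node-feature space and chained by matrix multiplication —
    a completely different code path from the package's edge-wise backprop.
    """
    P = emb.coords
    P0 = np.broadcast_to((0.0 - emb.gene_means) @ emb.components.T, P.shape)
    _, _, _, graphs = _forward_cached(model, P)
    m = P.shape[0]

    def forward_zs(feats):
        H = feats.copy()
        zs = []
        for layer, graph in zip(model.layers, graphs):
            E = graph.targets.size
            Z = np.zeros((E, layer.f_out))
            for e, (i, j) in enumerate(zip(graph.targets, graph.sources)):
                pair = np.concatenate([H[i], H[j] - H[i]])
                Z[e] = layer.theta @ pair + layer.bias
            zs.append(Z)
            H_new = np.zeros((m, layer.f_out))
            for e, i in enumerate(graph.targets):
                H_new[i] += silu(Z[e])
            H = H_new
        return zs

    zs, z0s = forward_zs(np.asarray(P)), forward_zs(np.asarray(P0))
    f_in = P.shape[1]
    M = np.eye(m * f_in)
    for layer, graph, Z, Z0 in zip(model.layers, graphs, zs, z0s):
        E, f_out = graph.targets.size, layer.f_out
        th_a, th_b = layer.theta[:, :f_in], layer.theta[:, f_in:]
        L = np.zeros((E * f_out, m * f_in))
        for e, (i, j) in enumerate(zip(graph.targets, graph.sources)):
            L[e * f_out : (e + 1) * f_out, i * f_in : (i + 1) * f_in] += th_a - th_b
            L[e * f_out : (e + 1) * f_out, j * f_in : (j + 1) * f_in] += th_b
        dZ = (Z - Z0).ravel()
        small = np.abs(dZ) < 1e-7
        mult = np.where(
            small,
            silu_grad(Z).ravel(),
            (silu(Z) - silu(Z0)).ravel() / np.where(small, 1.0, dZ),
        )
        agg = np.zeros((m * f_out, E * f_out))
        for e, i in enumerate(graph.targets):
            agg[i * f_out : (i + 1) * f_out, e * f_out : (e + 1) * f_out] = np.eye(
                f_out
            )
        M = agg @ np.diag(mult) @ L @ M
        f_in = f_out
    C = model.n_classes
    final = np.zeros((m * C, m * f_in))
    for i in range(m):
        final[i * C : (i + 1) * C, i * f_in : (i + 1) * f_in] = model.out_weight
    M = final @ M
    seed_vec = np.zeros(m * C)
    seed_vec[np.arange(m) * C + targets] = 1.0
    M_pc = (seed_vec @ M).reshape(m, P.shape[1])
    return (M_pc @ emb.components) * X.values


class TestDenseOracle:
    def test_matches_independent_multiplier_matrix_implementation(self):
        model, emb, norm, targets = _toy_problem(n=8, g=12, d=5, seed=4)
        A = slp.deeplift_attribute(model, emb, norm, targets)
        expected = _dense_deeplift(model, emb, norm, targets)
        np.testing.assert_allclose(A.scores, expected, rtol=1e-4, atol=1e-10)


class TestAggregateImportance:
    def test_hand_arithmetic(self):
        A = AttributionMatrix(
            np.array([[1.0, -1.0], [3.0, 1.0]]), np.zeros(2, dtype=int), ["g1", "g2"]
        )
        imp = slp.aggregate_importance(A, np.zeros(2, dtype=int), ["T0"])
        # means (2, 0) -> abs (2, 0) -> sd 1 -> unchanged
        np.testing.assert_allclose(imp.importance, [[2.0, 0.0]])
        assert imp.degenerate == []

    def test_degenerate_constant_row_flagged_not_scaled(self):
        A = AttributionMatrix(
            np.array([[1.0, 1.0], [1.0, 1.0]]), np.zeros(2, dtype=int), ["g1", "g2"]
        )
        imp = slp.aggregate_importance(A, np.zeros(2, dtype=int), ["T0"])
        np.testing.assert_allclose(imp.importance, [[1.0, 1.0]])
        assert imp.degenerate == ["T0"]

    def test_matches_brute_force_on_random_toy(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(30, 7))
        labels = rng.integers(0, 3, size=30)
        A = AttributionMatrix(scores, labels, [f"g{j}" for j in range(7)])
        imp = slp.aggregate_importance(A, labels, ["T0", "T1", "T2"])
        for t_idx, name in enumerate(["T0", "T1", "T2"]):
            row = np.abs(scores[labels == t_idx].mean(axis=0))
            row = row / row.std()
            np.testing.assert_allclose(imp.importance[t_idx], row, atol=1e-12)

    def test_empty_type_row_omitted(self):
        A = AttributionMatrix(
            np.ones((3, 2)), np.zeros(3, dtype=int), ["g1", "g2"]
        )
        imp = slp.aggregate_importance(A, np.zeros(3, dtype=int), ["T0", "T1"])
        assert imp.cell_types == ["T0"]


class TestTopGenesAndMarkers:
    def _table(self, rows, genes):
        return ImportanceTable(
            np.asarray(rows, dtype=float),
            [f"T{i}" for i in range(len(rows))],
            genes,
        )

    def test_ranking_and_tie_rule(self):
        imp = self._table([[0.1, 5.0, 3.0]], ["g1", "g2", "g3"])
        assert slp.top_genes(imp, 2) == {"T0": ["g2", "g3"]}
        tied = self._table([[5.0, 5.0, 1.0]], ["zz", "aa", "mm"])
        assert slp.top_genes(tied, 2) == {"T0": ["aa", "zz"]}

    def test_request_beyond_vocabulary_truncates(self):
        imp = self._table([[1.0, 2.0]], ["g1", "g2"])
        assert slp.top_genes(imp, 10) == {"T0": ["g2", "g1"]}

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{j:03d}" for j in range(40)]
        row = rng.normal(size=40)
        imp = self._table([row], genes)
        expected = [g for _, g in sorted(zip(-row, genes))]
        assert slp.top_genes(imp, 40)["T0"] == expected

    def test_augment_skips_existing_markers(self):
        imp = self._table([[4.0, 3.0, 2.0, 1.0]], ["g1", "g2", "g3", "g4"])
        out = slp.augment_markers({"T0": ["g1"]}, imp, n_add=3)
        assert out == {"T0": ["g1", "g2", "g3", "g4"]}

    def test_zero_additions_is_identity(self):
        imp = self._table([[1.0, 2.0]], ["g1", "g2"])
        assert slp.augment_markers({"T0": ["g2"]}, imp, n_add=0) == {"T0": ["g2"]}

    def test_unknown_marker_gene_rejected(self):
        imp = self._table([[1.0, 2.0]], ["g1", "g2"])
        with pytest.raises(ValueError, match="vocabulary"):
            slp.augment_markers({"T0": ["nope"]}, imp)
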