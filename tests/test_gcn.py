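"""EdgeConv layers, the full forward pass, training and model selection."""

import numpy as np
import pytest

import sclabelprop as slp
from sclabelprop.gcn import (
    EdgeConvLayer,
    GCNConfig,
    GCNModel,
    silu,
)
from tests.conftest import make_embedding


def _silu(x):
    return x / (1.0 + np.exp(-x))


class TestEdgeConvForward:
    def test_zero_parameters_give_zero_output(self):
        graph = slp.build_knn_graph(np.arange(4.0)[:, None], k=1)
        layer = EdgeConvLayer(np.zeros((3, 2)), np.zeros(3))
        out = slp.edgeconv_forward(np.arange(4.0)[:, None], graph, layer)
        assert (out == 0).all()

    def test_self_loop_only_node_reduces_to_silu(self):
        # single node, k=0: pair feature is (x, 0), theta=(1,1) -> SiLU(x)
        graph = slp.build_knn_graph(np.array([[1.7]]), k=0)
        layer = EdgeConvLayer(np.array([[1.0, 1.0]]), np.zeros(1))
        out = slp.edgeconv_forward(np.array([[1.7]]), graph, layer)
        np.testing.assert_allclose(out, [[_silu(1.7)]], atol=1e-12)

    def test_two_node_hand_computation(self):
        # x = (1, 2), k=1, theta=(1, 0): every edge sees z = x_i, so each
        # node sums two identical SiLU terms
        x = np.array([[1.0], [2.0]])
        graph = slp.build_knn_graph(x, k=1)
        layer = EdgeConvLayer(np.array([[1.0, 0.0]]), np.zeros(1))
        out = slp.edgeconv_forward(x, graph, layer)
        np.testing.assert_allclose(
            out, [[2 * 0.731059], [2 * 1.761594]], atol=1e-5
        )

    def test_width_mismatch_is_an_error(self):
        graph = slp.build_knn_graph(np.zeros((3, 2)), k=1)
        layer = EdgeConvLayer(np.zeros((3, 6)), np.zeros(3))
        with pytest.raises(ValueError, match="width"):
            slp.edgeconv_forward(np.zeros((3, 2)), graph, layer)


class TestGCNForward:
    def _model(self, in_dim=4, n_classes=3, seed=0, **kw):
        cfg = GCNConfig(batch_size=10, n_neighbors=2, embed_dim=8, seed=seed, **kw)
        return GCNModel.initialize(in_dim, n_classes, cfg, np.random.default_rng(seed))

    def test_zero_parameter_model_outputs_bias(self):
        model = self._model()
        for layer in model.layers:
            layer.theta[:] = 0
            layer.bias[:] = 0
        model.out_weight[:] = 0
        model.out_bias[:] = [1.0, -2.0, 0.5]
        scores = slp.gcn_forward(model, np.random.default_rng(0).normal(size=(6, 4)))
        np.testing.assert_allclose(scores, np.tile([1.0, -2.0, 0.5], (6, 1)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        model = self._model(seed=3)
        X = rng.normal(size=(12, 4))
        perm = rng.permutation(12)
        base = slp.gcn_forward(model, X)
        permuted = slp.gcn_forward(model, X[perm])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-5)

    def test_single_layer_composes_edgeconv_plus_linear(self):
        model = self._model(n_layers=1)
        X = np.random.default_rng(1).normal(size=(5, 4))
        graph = slp.build_knn_graph(X, model.config.n_neighbors)
        by_hand = (
            slp.edgeconv_forward(X, graph, model.layers[0]) @ model.out_weight.T
            + model.out_bias
        )
        np.testing.assert_allclose(slp.gcn_forward(model, X), by_hand, atol=1e-10)


class TestSplitValidation:
    def _labels(self, per_class=25, n_classes=4, n_unconf=30):
        labels = np.concatenate(
            [np.full(per_class, c) for c in range(n_classes)]
            + [np.full(n_unconf, -1)]
        )
        return slp.ConsensusLabels(labels, 0.51, [f"T{c}" for c in range(n_classes)])

    def test_stratified_eighty_twenty(self):
        c = self._labels()
        train, val = slp.split_validation(c, 0.20, seed=0)
        assert val.sum() == 20 and train.sum() == 80
        for cls in range(4):
            assert val[c.labels == cls].sum() == 5

    def test_unconfident_cells_in_neither_mask(self):
        c = self._labels()
        train, val = slp.split_validation(c, 0.20, seed=0)
        assert not train[c.labels < 0].any()
        assert not val[c.labels < 0].any()
        assert not (train & val).any()

    def test_zero_fraction_and_determinism(self):
        c = self._labels()
        _, val = slp.split_validation(c, 0.0, seed=1)
        assert val.sum() == 0
        a = slp.split_validation(c, 0.2, seed=5)
        b = slp.split_validation(c, 0.2, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_class_stays_in_train(self):
        labels = np.array([0] * 20 + [1])
        c = slp.ConsensusLabels(labels, 0.51, ["A", "B"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            train, val = slp.split_validation(c, 0.2, seed=0)
        assert train[c.labels == 1].all()


def _two_cluster_problem(n=100, seed=0, confident_frac=0.5):
    """Two Gaussian clusters 10 sigma apart; half the cells labeled."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [10.0, 10.0]])
    truth = rng.integers(0, 2, size=n)
    coords = centers[truth] + rng.normal(scale=1.0, size=(n, 2))
    labels = truth.copy()
    labels[rng.random(n) > confident_frac] = -1
    c = slp.ConsensusLabels(labels, 0.51, ["A", "B"])
    return make_embedding(coords), c, truth


class TestTraining:
    def test_zero_epochs_returns_seeded_initialization(self):
        emb, c, _ = _two_cluster_problem()
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=0, seed=9)
        model, log = slp.train_gcn(emb, c, cfg)
        expected = GCNModel.initialize(2, 2, cfg, np.random.default_rng(9))
        for got, want in zip(model.parameters(), expected.parameters()):
            np.testing.assert_array_equal(got, want)
        assert log.losses.size == 0

    def test_separable_clusters_reach_perfect_accuracy(self):
        emb, c, truth = _two_cluster_problem(seed=1)
        cfg = GCNConfig(
            batch_size=20, n_neighbors=2, n_layers=2, embed_dim=25,
            epochs=150, seed=1,
        )
        model, log = slp.train_gcn(emb, c, cfg)
        pred, _ = slp.predict_labels(model, emb)
        assert slp.evaluate_accuracy(pred, truth) == 1.0
        # early loss trajectory is non-increasing up to jitter
        early = log.losses[:10]
        assert (np.diff(early) <= 1e-3).all()

    def test_loss_never_touches_validation_or_unconfident_cells(self):
        emb, c, _ = _two_cluster_problem(seed=2)
        train_mask, val_mask = slp.split_validation(c, 0.3, seed=2)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=3, seed=2)
        _, log = slp.train_gcn(emb, c, cfg, train_mask=train_mask)
        eligible = (c.labels >= 0) & train_mask
        assert not log.loss_cells_used[~eligible].any()
        assert not log.loss_cells_used[val_mask].any()
        # every eligible cell participates (each epoch shuffles all cells in)
        assert log.loss_cells_used[eligible].all()

    def test_training_is_deterministic_given_seed(self):
        emb, c, _ = _two_cluster_problem(seed=4)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=5, seed=7)
        m1, l1 = slp.train_gcn(emb, c, cfg)
        m2, l2 = slp.train_gcn(emb, c, cfg)
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(l1.losses, l2.losses)


class TestPredictAndEvaluate:
    def test_predict_matches_forward_argmax(self):
        emb, c, _ = _two_cluster_problem(seed=5)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=2, seed=5)
        model, _ = slp.train_gcn(emb, c, cfg)
        pred, scores = slp.predict_labels(model, emb)
        np.testing.assert_array_equal(pred, scores.argmax(axis=1))
        pred2, _ = slp.predict_labels(model, emb)
        np.testing.assert_array_equal(pred, pred2)

    def test_accuracy_matches_brute_force_count(self):
        rng = np.random.default_rng(6)
        pred = rng.integers(0, 4, size=1000)
        truth = rng.integers(0, 4, size=1000)
        brute = sum(1 for p, t in zip(pred, truth) if p == t) / 1000
        assert slp.evaluate_accuracy(pred, truth) == brute

    def test_unknown_predictions_count_as_incorrect(self):
        pred = np.full(10, slp.UNKNOWN)
        truth = np.zeros(10, dtype=int)
        assert slp.evaluate_accuracy(pred, truth) == 0.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            slp.evaluate_accuracy(np.zeros(3), np.zeros(3), np.zeros(3, dtype=bool))


class TestGridSearchAndMultiSeed:
    def test_single_and_tied_grids(self):
        emb, c, _ = _two_cluster_problem(seed=8)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=2, seed=8)
        best, results = slp.grid_search(emb, c, [cfg], seed=8)
        assert best.embed_dim == 25 and len(results) == 1
        best2, results2 = slp.grid_search(emb, c, [cfg, cfg], seed=8)
        assert results2[0]["val_accuracy"] == results2[1]["val_accuracy"]
        assert best2 is results2[0]["config"]

    def test_separable_grid_reaches_perfect_validation(self):
        emb, c, _ = _two_cluster_problem(seed=9)
        grid = [
            GCNConfig(batch_size=20, n_neighbors=2, n_layers=l, embed_dim=25,
                      epochs=300, seed=9)
            for l in (1, 2)
        ]
        best, results = slp.grid_search(emb, c, grid, seed=9)
        assert results[0]["val_accuracy"] == 1.0
        assert best is results[0]["config"]  # tie-break to grid head

    def test_multi_seed_report_stats(self):
        emb, c, truth = _two_cluster_problem(seed=10)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=120, seed=10)
        single = slp.multi_seed_report(emb, c, cfg, truth, n_runs=1)
        assert single["total"]["sd"] == 0.0
        report = slp.multi_seed_report(emb, c, cfg, truth, n_runs=3)
        assert report["total"]["mean"] == 1.0 and report["total"]["sd"] == 0.0
        again = slp.multi_seed_report(emb, c, cfg, truth, n_runs=3)
        assert report["total"] == again["total"]
        for p, q in zip(report["predictions"], again["predictions"]):
            np.testing.assert_array_equal(p, q)


class TestMonotoneDegradation:
    def test_accuracy_does_not_improve_with_fewer_confident_labels(self):
        """Shrinking the confident seed set from 70% to 30% to 10% of cells
        never raises mean accuracy by more than noise (5 seeds, 0.05 slack)."""
        means = []
        for frac in (0.7, 0.3, 0.1):
            accs = []
            for seed in range(5):
                emb, c, truth = _two_cluster_problem(
                    n=120, seed=seed, confident_frac=frac
                )
                cfg = GCNConfig(
                    batch_size=20, n_neighbors=2, embed_dim=25, epochs=60, seed=seed
                )
                model, _ = slp.train_gcn(emb, c, cfg)
                pred, _ = slp.predict_labels(model, emb)
                accs.append(slp.evaluate_accuracy(pred, truth))
            means.append(np.mean(accs))
        assert means[1] <= means[0] + 0.05
        assert means[2] <= means[1] + 0.05


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        emb, c, _ = _two_cluster_problem(seed=11)
        cfg = GCNConfig(batch_size=20, n_neighbors=2, embed_dim=25, epochs=2, seed=11)
        model, _ = slp.train_gcn(emb, c, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = slp.GCNModel.load(path)
        assert loaded.config == model.config
        for a, b in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(
            slp.predict_labels(loaded, emb)[0], slp.predict_labels(model, emb)[0]
        )
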