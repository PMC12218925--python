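import numpy as np
import pytest

from cytohgnn import (
    GCNClassifier,
    HGNNConfig,
    HypergraphClassifier,
    build_hypergraph,
    gcn_operator,
    propagation_operator,
    stratified_holdout,
)
from cytohgnn.classifier import (
    ablate_propagation,
    init_parameters,
    loss_and_grads,
    model_forward,
)
from cytohgnn.exceptions import DegenerateInputError, InvalidConfigError
from cytohgnn.nn_ops import bn_forward, relu, softmax


class TestInitAndForward:
    def test_default_parameter_shapes(self):
        params = init_parameters(HGNNConfig())
        assert params["Theta1"].shape == (2304, 32)
        assert params["Theta2"].shape == (32, 32)
        assert params["W_fc"].shape == (32, 5)

    def test_same_seed_identical_parameters(self):
        a = init_parameters(HGNNConfig(seed=11))
        b = init_parameters(HGNNConfig(seed=11))
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_softmax_rows_sum_to_one(self, rng):
        cfg = HGNNConfig(in_dim=8, hidden_dim=4, n_classes=3)
        params = init_parameters(cfg)
        X = rng.normal(size=(10, 8))
        P = propagation_operator(build_hypergraph(X, 3))
        probs = model_forward(params, P, X, cfg)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            HGNNConfig(dropout=1.0)
        with pytest.raises(InvalidConfigError):
            HGNNConfig(learning_rate=0.0)
        with pytest.raises(InvalidConfigError):
            HGNNConfig(epochs=0)

    def test_ablation_arm_ignores_hypergraph_structure(self, rng):
        """With propagation off, output is identical for any hypergraph."""
        cfg = HGNNConfig(in_dim=6, hidden_dim=4, n_classes=3, propagation=False)
        X = rng.normal(size=(12, 6))
        y = rng.integers(0, 3, 12)
        out = []
        for k in (2, 5, 11):
            model = HypergraphClassifier(X, y, k=k, config=cfg)
            probs = model_forward(
                init_parameters(cfg), model.operator, X, cfg
            )
            out.append(probs)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[0], out[2])

    def test_forward_matches_stagewise_composition(self, rng):
        """Inference forward equals an independent step-by-step script:
        two hypergraph convolutions with BN/ReLU then the affine head."""
        cfg = HGNNConfig(in_dim=4, hidden_dim=3, n_classes=2, dropout=0.5)
        X = rng.normal(size=(6, 4))
        operator = propagation_operator(build_hypergraph(X, 2))
        P = operator.dense()
        params = init_parameters(cfg, np.random.default_rng(5))
        probs = model_forward(params, operator, X, cfg, training=False)

        def bn_eval(z, name):
            return (
                (z - params[f"{name}_mean"])
                / np.sqrt(params[f"{name}_var"] + cfg.bn_eps)
            ) * params[f"{name}_gamma"] + params[f"{name}_beta"]

        h1 = relu(bn_eval(P @ X @ params["Theta1"], "bn1"))
        h2 = relu(bn_eval(P @ h1 @ params["Theta2"], "bn2"))
        expected = softmax(h2 @ params["W_fc"] + params["b_fc"])
        np.testing.assert_allclose(probs, expected, atol=1e-12)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Numerical vs analytic gradient of the masked cross-entropy on an
        N=5 instance agrees to 1e-4 relative error for every parameter."""
        rng = np.random.default_rng(3)
        X = rng.random((5, 6))
        y = np.array([0, 1, 2, 0, 1])
        mask = np.array([True, True, True, True, False])
        P = propagation_operator(build_hypergraph(X, 2))
        cfg = HGNNConfig(in_dim=6, hidden_dim=4, n_classes=3, dropout=0.0)
        params = init_parameters(cfg)
        _, grads = loss_and_grads(params, P, X, y, mask, cfg)
        eps = 1e-6
        for key in grads:
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                p0 = params[key][ix]
                params[key][ix] = p0 + eps
                lp, _ = loss_and_grads(params, P, X, y, mask, cfg)
                params[key][ix] = p0 - eps
                lm, _ = loss_and_grads(params, P, X, y, mask, cfg)
                params[key][ix] = p0
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num) + abs(grads[key][ix]), 1e-8)
                assert abs(num - grads[key][ix]) / denom < 1e-4, key


@pytest.fixture(scope="module")
def fitted(separable_table):
    plan = stratified_holdout(separable_table.labels, seed=0)
    model = HypergraphClassifier.from_feature_table(separable_table, k=10)
    return model, plan, model.fit(plan.train_idx, plan.val_idx)


class TestTraining:
    def test_label_recovery_on_separable_clusters(self, fitted):
        """8-sigma separation, default hyperparameters, k=10: held-out
        accuracy reaches 0.99."""
        model, plan, result = fitted
        report = result.evaluate(plan.test_idx)
        assert report.accuracy >= 0.99

    def test_loss_decreases_over_training(self, fitted):
        _, _, result = fitted
        h = result.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_predictions_match_generating_labels(self, fitted):
        model, plan, result = fitted
        pred = result.predict(plan.test_idx)
        assert np.mean(pred == model.labels[plan.test_idx]) >= 0.99

    def test_identical_seed_identical_logs(self, separable_table):
        plan = stratified_holdout(separable_table.labels, seed=1)
        cfg = HGNNConfig(in_dim=separable_table.n_features, n_classes=5, epochs=30, seed=4)
        logs = []
        for _ in range(2):
            model = HypergraphClassifier.from_feature_table(
                separable_table, k=10, config=cfg
            )
            logs.append(model.fit(plan.train_idx, plan.val_idx).history)
        np.testing.assert_array_equal(
            logs[0].to_numpy(), logs[1].to_numpy()
        )

    def test_summary_mentions_fit_quality(self, fitted):
        _, _, result = fitted
        text = result.summary()
        assert "best val accuracy" in text
        assert "hidden dim" in text

    def test_overlapping_masks_rejected(self, separable_table):
        model = HypergraphClassifier.from_feature_table(separable_table, k=5)
        idx = np.arange(50)
        with pytest.raises(DegenerateInputError):
            model.fit(idx, idx)

    def test_empty_mask_rejected(self, separable_table):
        model = HypergraphClassifier.from_feature_table(separable_table, k=5)
        with pytest.raises(DegenerateInputError):
            model.fit(np.arange(50), np.array([], dtype=int))

    def test_missing_class_in_train_mask_rejected(self, separable_table):
        model = HypergraphClassifier.from_feature_table(separable_table, k=5)
        with pytest.raises(DegenerateInputError):
            # first class only occupies indices 0..99
            model.fit(np.arange(100), np.arange(100, 120))


class TestPredict:
    def test_argmax_and_tie_break(self):
        probs = np.array([[0.1, 0.7, 0.2, 0.0, 0.0], [0.2, 0.2, 0.2, 0.2, 0.2]])
        assert np.argmax(probs[0]) == 1
        assert np.argmax(probs[1]) == 0  # uniform ties resolve to class 0


class TestAblation:
    def test_k0_propagation_equals_no_propagation(self, rng):
        """On a self-loop-only hypergraph P = I, so both arms coincide."""
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 2, 40)
        outs = []
        for propagate in (True, False):
            cfg = HGNNConfig(
                in_dim=8, hidden_dim=4, n_classes=2, epochs=10,
                dropout=0.0, propagation=propagate, seed=0,
            )
            model = HypergraphClassifier(X, y, k=0, config=cfg)
            result = model.fit(np.arange(20), np.arange(20, 30))
            outs.append(result.predict_proba())
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-10)

    def test_paired_reports_share_protocol_fields(self, overlapping_table):
        plan = stratified_holdout(overlapping_table.labels, seed=0)
        cfg = HGNNConfig(
            in_dim=overlapping_table.n_features, n_classes=5, epochs=40, seed=0
        )
        rep_with, rep_without = ablate_propagation(
            overlapping_table.features,
            overlapping_table.labels,
            plan.train_idx, plan.val_idx, plan.test_idx,
            k=10, config=cfg,
        )
        for rep in (rep_with, rep_without):
            assert set(rep.macro) == {"specificity", "precision", "recall", "f1"}
            assert 0 <= rep.accuracy <= 1
            assert rep.per_class.shape == (5, 4)


class TestGCN:
    def test_k0_operator_is_identity(self, rng):
        X = rng.normal(size=(9, 4))
        np.testing.assert_allclose(gcn_operator(X, 0).toarray(), np.eye(9))

    def test_gcn_recovers_separable_clusters(self, separable_table):
        plan = stratified_holdout(separable_table.labels, seed=0)
        cfg = HGNNConfig(
            in_dim=separable_table.n_features, n_classes=5, epochs=100, seed=0
        )
        model = GCNClassifier(
            separable_table.features, separable_table.labels, k=10, config=cfg
        )
        result = model.fit(plan.train_idx, plan.val_idx)
        assert result.evaluate(plan.test_idx).accuracy >= 0.95

    def test_gcn_operator_symmetric_with_self_loops(self, rng):
        X = rng.normal(size=(15, 3))
        A = gcn_operator(X, 4).toarray()
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert (np.diag(A) > 0).all()
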