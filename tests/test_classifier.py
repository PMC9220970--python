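"""MLP mechanics: initialization, gradients, training, persistence, inference."""

import json

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from ssca import (
    NetworkLayout,
    TrainConfig,
    WindowConfig,
    forward,
    init_mlp,
    load_model,
    make_helix,
    predict_chain,
    save_model,
    train,
    trace_from_coords,
)
from ssca.classifier import loss_and_gradients, predict_labels
from ssca.errors import DegenerateTrainingError, ModelFileError, SscaError

from conftest import random_rigid_motion


def _toy_blobs(n_per_class=100, seed=0):
    """Two well-separated 2-feature Gaussian blobs mapped to H and C."""
    rng = np.random.default_rng(seed)
    a = rng.normal(loc=(-3, -3), scale=0.5, size=(n_per_class, 2))
    b = rng.normal(loc=(3, 3), scale=0.5, size=(n_per_class, 2))
    return np.vstack([a, b]), "H" * n_per_class + "C" * n_per_class


def _tiny_model(input_width=2, hidden=(8,), seed=0):
    return init_mlp(NetworkLayout(input_width=input_width, hidden=hidden), seed=seed)


class TestInit:
    def test_deterministic_per_seed(self):
        layout = NetworkLayout(input_width=47)
        m1, m2 = init_mlp(layout, seed=4), init_mlp(layout, seed=4)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        m3 = init_mlp(layout, seed=5)
        assert any(not np.array_equal(a, b) for a, b in zip(m1.weights, m3.weights))

    def test_layer_shapes(self):
        m = init_mlp(NetworkLayout(input_width=47, hidden=(128, 128)), seed=0)
        assert len(m.weights) == 3
        assert [w.shape for w in m.weights] == [(47, 128), (128, 128), (128, 3)]

    def test_default_layout(self):
        layout = NetworkLayout(input_width=79)
        assert layout.hidden == (128, 128) and layout.output_width == 3

    def test_output_width_fixed(self):
        with pytest.raises(SscaError):
            NetworkLayout(input_width=10, output_width=4)


class TestForward:
    def test_zeroed_output_layer_gives_uniform(self):
        m = _tiny_model()
        m.weights[-1][:] = 0.0
        m.biases[-1][:] = 0.0
        np.testing.assert_allclose(forward(m, [1.0, -2.0]), [1 / 3] * 3, atol=1e-12)

    def test_probabilities_normalized(self):
        m = _tiny_model(input_width=5, hidden=(16, 16), seed=2)
        X = np.random.default_rng(0).normal(size=(1000, 5)) * 10
        np.testing.assert_allclose(forward(m, X).sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(SscaError, match="feature dimension"):
            forward(_tiny_model(), [1.0, 2.0, 3.0])


class TestGradients:
    def test_analytic_matches_central_difference(self):
        """Every weight and bias gradient to 1e-5 relative on a 5-sample batch."""
        rng = np.random.default_rng(12)
        m = _tiny_model(input_width=4, hidden=(6, 5), seed=3)
        X = rng.normal(size=(5, 4))
        Y = np.eye(3)[rng.integers(0, 3, size=5)]
        _, gW, gb = loss_and_gradients(m, X, Y)
        eps = 1e-6
        for params, grads in ((m.weights, gW), (m.biases, gb)):
            for arr, grad in zip(params, grads):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp, _, _ = loss_and_gradients(m, X, Y)
                    arr[idx] = orig - eps
                    lm, _, _ = loss_and_gradients(m, X, Y)
                    arr[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestTrain:
    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = _toy_blobs()
        result = train(_tiny_model(seed=1), X, y, TrainConfig(epochs=200, seed=1))
        pred = predict_labels(result.model, X)
        assert np.mean(np.array(list(pred)) == np.array(list(y))) == 1.0
        # independent oracle on the same toy: a linear model also separates it
        ref = LogisticRegression().fit(X, list(y))
        assert ref.score(X, list(y)) == 1.0

    def test_loss_decreases(self):
        X, y = _toy_blobs(seed=5)
        result = train(_tiny_model(seed=2), X, y, TrainConfig(epochs=50, seed=2))
        h = result.loss_history
        assert h.shape == (50,)
        assert np.mean(h[-10:]) < np.mean(h[:10])

    def test_fixed_seed_bit_reproducible(self):
        X, y = _toy_blobs(seed=9)
        cfg = TrainConfig(epochs=20, seed=7)
        r1 = train(_tiny_model(seed=7), X, y, cfg)
        r2 = train(_tiny_model(seed=7), X, y, cfg)
        for w1, w2 in zip(r1.model.weights, r2.model.weights):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(r1.loss_history, r2.loss_history)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(DegenerateTrainingError):
            train(_tiny_model(), X, "H" * 30, TrainConfig(epochs=1))

    def test_group_split_keeps_groups_together(self):
        X, y = _toy_blobs(n_per_class=50)
        groups = np.repeat(np.arange(20), 5)
        result = train(_tiny_model(seed=3), X, y, TrainConfig(epochs=5, seed=3), groups=groups)
        train_groups = set(groups[result.train_indices])
        val_groups = set(groups[result.val_indices])
        assert not (train_groups & val_groups)

    def test_standardization_from_training_rows_only(self):
        X, y = _toy_blobs(seed=4)
        result = train(_tiny_model(seed=4), X, y, TrainConfig(epochs=5, seed=4))
        expected_mean = X[result.train_indices].mean(axis=0)
        np.testing.assert_allclose(result.model.feature_mean, expected_mean)
        assert np.all(result.model.feature_std > 0)


class TestPersistence:
    def test_roundtrip_preserves_forward_outputs(self, tmp_path):
        wc = WindowConfig(n=7)
        m = init_mlp(NetworkLayout(input_width=wc.width), seed=6, window_config=wc)
        path = tmp_path / "model.json"
        save_model(m, path)
        again = load_model(path)
        X = np.random.default_rng(1).normal(size=(100, wc.width))
        np.testing.assert_allclose(forward(again, X), forward(m, X), atol=1e-12)

    def test_truncated_file_rejected(self, tmp_path):
        wc = WindowConfig(n=5)
        m = init_mlp(NetworkLayout(input_width=wc.width), seed=0, window_config=wc)
        path = tmp_path / "model.json"
        save_model(m, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_inconsistent_width_rejected(self, tmp_path):
        wc = WindowConfig(n=5)
        m = init_mlp(NetworkLayout(input_width=wc.width), seed=0, window_config=wc)
        path = tmp_path / "model.json"
        save_model(m, path)
        doc = json.loads(path.read_text())
        doc["layout"]["input_width"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFileError, match="model file error"):
            load_model(path)

    def test_wrong_version_rejected(self, tmp_path):
        wc = WindowConfig(n=5)
        m = init_mlp(NetworkLayout(input_width=wc.width), seed=0, window_config=wc)
        path = tmp_path / "model.json"
        save_model(m, path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFileError, match="version"):
            load_model(path)


class TestPredictChain:
    def test_helix_interior_all_h_with_coil_termini(self, trained_model):
        trace, _ = make_helix(40)
        assignment = predict_chain(trained_model, trace)
        n = trained_model.window_config.n  # 11 -> 5 windowless residues per end
        half = (n - 1) // 2
        assert assignment.labels[:half] == "C" * half
        assert assignment.labels[-half:] == "C" * half
        assert set(assignment.labels[half:-half]) == {"H"}
        np.testing.assert_allclose(assignment.probabilities[0], [0, 0, 1])

    def test_short_trace_all_coil_with_warning(self, trained_model):
        trace, _ = make_helix(8)
        with pytest.warns(UserWarning):
            assignment = predict_chain(trained_model, trace)
        assert assignment.labels == "C" * 8

    def test_prediction_invariant_under_rigid_motion(self, trained_model):
        rng = np.random.default_rng(31)
        trace, _ = make_helix(30)
        ref = predict_chain(trained_model, trace).labels
        for _ in range(5):
            R, t = random_rigid_motion(rng)
            moved = trace_from_coords(trace.coords @ R.T + t)
            assert predict_chain(trained_model, moved).labels == ref
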