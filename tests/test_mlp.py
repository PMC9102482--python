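"""Softmax MLP: forward pass, loss, gradients, training, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myohmi as m
from myohmi.mlp import MlpModel, Scaler, _loss_and_grads, softmax


def _zero_model(scaler=True):
    sc = Scaler(np.zeros(4), np.ones(4)) if scaler else None
    return MlpModel(np.zeros((4, 4)), np.zeros(4), np.zeros((4, 4)),
                    np.zeros(4), sc)


class TestForward:
    def test_zero_weights_uniform_output(self):
        p = m.mlp_forward(_zero_model(), np.ones(4))
        np.testing.assert_allclose(p, 0.25, atol=1e-15)

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=4,
                    max_size=4))
    @settings(derandomize=True, max_examples=100)
    def test_probability_simplex(self, x):
        rng = np.random.default_rng(0)
        model = MlpModel(rng.normal(size=(4, 4)), rng.normal(size=4),
                         rng.normal(size=(4, 4)), rng.normal(size=4))
        p = m.mlp_forward(model, np.array(x))
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_dead_hidden_layer_outputs_softmax_of_bias(self):
        rng = np.random.default_rng(1)
        b2 = rng.normal(size=4)
        model = MlpModel(-np.ones((4, 4)), -np.ones(4) * 10,
                         rng.normal(size=(4, 4)), b2)
        p = m.mlp_forward(model, np.ones(4))  # all hidden pre-activations < 0
        np.testing.assert_allclose(p, softmax(b2), atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.mlp_forward(_zero_model(), np.ones(3))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(4)[[0, 1, 2, 3]]
        assert m.cross_entropy(y, np.clip(y, 1e-12, 1.0)) < 1e-10

    def test_uniform_prediction_ln4(self):
        y = np.eye(4)[[0, 3]]
        yhat = np.full((2, 4), 0.25)
        assert m.cross_entropy(y, yhat) == pytest.approx(np.log(4.0), abs=1e-12)

    @given(st.integers(0, 3))
    @settings(derandomize=True, max_examples=20)
    def test_nonnegative(self, k):
        rng = np.random.default_rng(k)
        p = rng.dirichlet(np.ones(4), size=8)
        y = np.eye(4)[rng.integers(0, 4, size=8)]
        assert m.cross_entropy(y, p) >= 0.0

    def test_zero_probability_clipped_with_warning(self):
        y = np.array([[1.0, 0, 0, 0]])
        yhat = np.array([[0.0, 0.5, 0.25, 0.25]])
        with pytest.warns(UserWarning, match="clipping"):
            loss = m.cross_entropy(y, yhat)
        assert np.isfinite(loss)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences to 1e-6 relative."""
        params = {
            "W1": rng.normal(scale=0.5, size=(4, 4)),
            "b1": rng.normal(scale=0.5, size=4),
            "W2": rng.normal(scale=0.5, size=(4, 4)),
            "b2": rng.normal(scale=0.5, size=4),
        }
        X = rng.normal(size=(12, 4))
        Y = np.eye(4)[rng.integers(0, 4, size=12)]
        _, grads, _ = _loss_and_grads(params, X, Y)
        h = 1e-6
        for key in params:
            flat = params[key].ravel()
            g_fd = np.empty_like(flat)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                lp, _, _ = _loss_and_grads(params, X, Y)
                flat[i] = orig - h
                lm, _, _ = _loss_and_grads(params, X, Y)
                flat[i] = orig
                g_fd[i] = (lp - lm) / (2 * h)
            np.testing.assert_allclose(grads[key].ravel(), g_fd, rtol=1e-5,
                                       atol=1e-8)


class TestTraining:
    def test_benchmark_accuracy_and_loss_trend(self, benchmark_fit):
        res = benchmark_fit
        assert res.test_accuracy >= 0.95
        loss = res.history["loss"]
        assert loss[-1] < loss[0]
        checkpoints = loss[::500]
        assert np.all(np.diff(checkpoints) <= 0)

    def test_seeded_determinism(self, benchmark_segments):
        clf = m.EmgClassifier.from_segments(benchmark_segments)
        cfg = m.TrainConfig(epochs=50)
        a = clf.fit(cfg)
        b = clf.fit(cfg)
        np.testing.assert_array_equal(a.mlp.W1, b.mlp.W1)
        np.testing.assert_array_equal(a.mlp.W2, b.mlp.W2)

    def test_confusion_only_between_adjacent_durations(self, benchmark_fit):
        """Errors, if any, stay between SMP3 and SMP5 — never SMP vs SMP5."""
        cm = benchmark_fit.confusion_matrix()
        assert cm.loc["SMP", "SMP5"] == 0
        assert cm.loc["SMP5", "SMP"] == 0
        mat = cm.to_numpy()
        off_diag = mat.sum() - np.trace(mat)
        adjacent = cm.loc["SMP3", "SMP5"] + cm.loc["SMP5", "SMP3"]
        assert off_diag - adjacent <= 0.05 * mat.sum()

    def test_missing_class_in_training_split_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.zeros(20, dtype=int)  # only NIM present
        with pytest.raises(ValueError, match="absent"):
            m.train_mlp(X, y, m.TrainConfig(epochs=5))

    def test_comparable_to_sklearn_baseline(self, benchmark_segments):
        """An off-the-shelf MLP on the same features also solves the task."""
        from sklearn.neural_network import MLPClassifier
        from sklearn.model_selection import train_test_split
        from sklearn.preprocessing import StandardScaler

        X = np.vstack([s.features for s in benchmark_segments])
        y = np.array([s.label.value for s in benchmark_segments])
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2,
                                              random_state=42)
        scaler = StandardScaler().fit(Xtr)
        ref = MLPClassifier(hidden_layer_sizes=(4,), max_iter=3000,
                            random_state=0).fit(scaler.transform(Xtr), ytr)
        assert ref.score(scaler.transform(Xte), yte) >= 0.9


class TestPredict:
    def test_argmax_class_and_pulse(self, benchmark_fit, benchmark_segments):
        seg = next(s for s in benchmark_segments
                   if s.label is m.ContractionClass.SMP5)
        cls, pulse = m.predict_class(benchmark_fit.mlp, seg)
        assert cls is m.ContractionClass.SMP5
        np.testing.assert_array_equal(pulse, [0, 0, 0, 1])

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="scaler"):
            m.predict_class(_zero_model(scaler=False), np.ones(4))

    def test_tie_resolves_to_lowest_index(self):
        model = _zero_model()  # uniform output: 4-way tie
        cls, pulse = m.predict_class(model, np.ones(4))
        assert cls is m.ContractionClass.NIM
        np.testing.assert_array_equal(pulse, [1, 0, 0, 0])

    def test_json_roundtrip(self, tmp_path, benchmark_fit):
        path = tmp_path / "model.json"
        benchmark_fit.mlp.to_json(path)
        back = m.MlpModel.from_json(path)
        np.testing.assert_allclose(back.W1, benchmark_fit.mlp.W1, atol=1e-15)
        np.testing.assert_allclose(back.scaler.mean, benchmark_fit.mlp.scaler.mean,
                                   atol=1e-15)
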