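import numpy as np
import pytest

from medgesture.errors import ConfigurationError
from medgesture.lstm import (
    ModelConfig,
    TrainedModel,
    forward,
    init_params,
    load_model,
    loss_and_grads,
    save_model,
    train,
)

TINY = ModelConfig(
    window_size=20, input_channels=3, lstm_units=8, dense_units=8,
    classes=4, epochs=3, batch_size=16, seed=0,
)


def tiny_data(n_per_class=12, seed=0, window=20):
    """Linearly separable 4-class sequences (distinct mean offsets)."""
    rng = np.random.default_rng(seed)
    X, Y = [], []
    offsets = [(-1, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for c, off in enumerate(offsets):
        x = 0.1 * rng.standard_normal((n_per_class, window, 3)) + np.array(off)
        X.append(x)
        y = np.zeros((n_per_class, 4))
        y[:, c] = 1
        Y.append(y)
    X, Y = np.concatenate(X), np.concatenate(Y)
    order = rng.permutation(len(X))
    return X[order], Y[order]


class TestBuild:
    def test_seeded_init_deterministic(self):
        a, b = init_params(TINY), init_params(TINY)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_output_is_probability_simplex(self):
        params = init_params(TINY)
        rng = np.random.default_rng(1)
        probs = forward(params, rng.standard_normal((7, 20, 3)), TINY)
        assert probs.shape == (7, 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_window_finite(self):
        probs = forward(init_params(TINY), np.zeros((1, 20, 3)), TINY)
        assert np.all(np.isfinite(probs))

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError):
            forward(init_params(TINY), np.zeros((1, 19, 3)), TINY)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(lstm_units=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(learning_rate=-1)


class TestGradients:
    def test_bptt_matches_numerical_gradient(self):
        """The analytic gradient of every parameter tensor agrees with a
        central-difference estimate — the independent oracle for the
        hand-written backpropagation through time."""
        cfg = ModelConfig(window_size=8, input_channels=3, lstm_units=5,
                          dense_units=6, classes=3, seed=0, l2_lambda=1e-3)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 8, 3))
        Y = np.eye(3)[rng.integers(0, 3, 4)]
        params = init_params(cfg)
        _, grads = loss_and_grads(params, X, Y, cfg)
        eps = 1e-6
        for k, v in params.items():
            for _ in range(3):  # spot-check a few entries per tensor
                idx = tuple(rng.integers(0, s) for s in v.shape)
                orig = v[idx]
                v[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, Y, cfg)
                v[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, Y, cfg)
                v[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), k


class TestTrain:
    def test_same_seed_identical_history(self):
        X, Y = tiny_data()
        cfg = TINY
        _, _, h1 = train(X[:32], Y[:32], X[32:], Y[32:], cfg)
        _, _, h2 = train(X[:32], Y[:32], X[32:], Y[32:], cfg)
        assert h1.train_accuracy == h2.train_accuracy
        assert h1.test_error == h2.test_error

    def test_learning_reduces_training_error(self):
        X, Y = tiny_data(n_per_class=16)
        cfg = ModelConfig(window_size=20, lstm_units=8, dense_units=8,
                          epochs=15, batch_size=16, seed=1)
        _, final, h = train(X[:48], Y[:48], X[48:], Y[48:], cfg)
        err = np.array(h.train_error)
        # non-increasing on average: compare 5-epoch moving-window means
        smoothed = np.convolve(err, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert len(h.train_accuracy) == cfg.epochs

    def test_l2_shrinks_weights(self):
        X, Y = tiny_data()
        base = ModelConfig(window_size=20, lstm_units=8, dense_units=8,
                           epochs=10, batch_size=16, seed=2, l2_lambda=0.0)
        ridge = ModelConfig(window_size=20, lstm_units=8, dense_units=8,
                            epochs=10, batch_size=16, seed=2, l2_lambda=0.05)
        _, f0, _ = train(X[:32], Y[:32], X[32:], Y[32:], base)
        _, f1, _ = train(X[:32], Y[:32], X[32:], Y[32:], ridge)
        norm = lambda m: sum(np.sum(v**2) for k, v in m.params.items() if k.startswith("W"))
        assert norm(f1) <= norm(f0)

    def test_empty_training_set_errors(self):
        with pytest.raises(ConfigurationError):
            train(np.zeros((0, 20, 3)), np.zeros((0, 4)),
                  np.zeros((1, 20, 3)), np.zeros((1, 4)), TINY)


class TestPredict:
    def _toy_model(self):
        X, Y = tiny_data()
        best, _, _ = train(X[:32], Y[:32], X[32:], Y[32:], TINY)
        return best, X[32:]

    def test_predict_deterministic_and_argmax(self):
        model, X = self._toy_model()
        out1, out2 = model.predict(X), model.predict(X)
        assert [l for l, _ in out1] == [l for l, _ in out2]
        for label, probs in out1:
            assert label == model.class_order[int(np.argmax(probs))]

    def test_exact_tie_breaks_to_first_class(self):
        cfg = TINY
        params = init_params(cfg)
        for k in params:  # zero weights -> uniform probabilities everywhere
            params[k] = np.zeros_like(params[k])
        model = TrainedModel(params, cfg)
        (label, probs), = model.predict(np.ones((1, 20, 3)))
        np.testing.assert_allclose(probs, 0.25)
        assert label == model.class_order[0]

    def test_save_load_round_trip(self, tmp_path):
        model, X = self._toy_model()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))
        assert back.config == model.config
        assert back.class_order == model.class_order

    def test_load_missing_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope")

    def test_version_mismatch(self, tmp_path):
        model, _ = self._toy_model()
        save_model(model, tmp_path / "m")
        cfg_file = tmp_path / "m" / "config.yaml"
        cfg_file.write_text(cfg_file.read_text().replace(
            "artifact_version: 1", "artifact_version: 99"))
        with pytest.raises(ConfigurationError, match="version"):
            load_model(tmp_path / "m")
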