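"""Backpropagation network tests: forward oracle, gradient check,
training behavior, serialization."""

import numpy as np
import pandas as pd
import pytest

from conftest import finite_difference_gradients
from doanet.bpnn import (
    NetworkConfig,
    backprop_step,
    forward,
    forward_batch,
    gradients,
    init_model,
    model_from_json,
    model_to_json,
    predict_index,
    train,
)
from doanet.features import INPUT_COLUMNS, TARGET_COLUMN, NormBounds


def _table(X, t):
    df = pd.DataFrame(X, columns=list(INPUT_COLUMNS))
    df[TARGET_COLUMN] = t
    return df


class TestForward:
    def test_zero_weights_give_half(self):
        model = init_model(NetworkConfig(init_scale=0.5, seed=0))
        for p in (model.w1, model.b1, model.w2, model.b2):
            p[...] = 0.0
        assert forward(model, np.full(7, 0.3)) == 0.5

    def test_output_strictly_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            model = init_model(NetworkConfig(seed=seed, init_scale=3.0))
            y = forward(model, rng.uniform(size=7))
            assert 0.0 < y < 1.0

    def test_matches_straight_line_matrix_oracle(self):
        """Independent re-computation: explicit loops over units."""
        model = init_model(NetworkConfig(seed=7))
        rng = np.random.default_rng(1)
        x = rng.uniform(size=7)
        h = np.empty(10)
        for j in range(10):
            z = model.b1[j] + sum(model.w1[j, k] * x[k] for k in range(7))
            h[j] = 1.0 / (1.0 + np.exp(-z))
        z_out = model.b2[0] + sum(model.w2[0, j] * h[j] for j in range(10))
        expected = 1.0 / (1.0 + np.exp(-z_out))
        assert forward(model, x) == pytest.approx(expected, abs=1e-12)
        assert forward_batch(model, x[None, :])[0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        model = init_model(NetworkConfig(seed=0))
        with pytest.raises(ValueError):
            forward(model, np.zeros(5))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Gradient check across random (weights, input, target) triples:
        worst-case error relative to the gradient scale below 1e-6."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            model = init_model(NetworkConfig(seed=trial))
            x = rng.uniform(size=7)
            t = rng.uniform()
            analytic = gradients(model, x, t)
            numeric = finite_difference_gradients(model, x, t)
            for a, n in zip(analytic, numeric):
                rel = np.max(np.abs(a - n)) / max(np.max(np.abs(n)), 1e-8)
                assert rel < 1e-6

    def test_zero_error_gives_zero_gradient(self):
        model = init_model(NetworkConfig(seed=3))
        x = np.full(7, 0.4)
        t = forward(model, x)
        for g in gradients(model, x, t):
            np.testing.assert_allclose(g, 0.0, atol=1e-15)


class TestBackpropStep:
    def test_momentum_free_step_descends(self):
        model = init_model(NetworkConfig(seed=1, momentum=0.0, learning_rate=0.5))
        x = np.full(7, 0.6)
        t = 0.9
        before = 0.5 * (forward(model, x) - t) ** 2
        backprop_step(model, x, t)
        after = 0.5 * (forward(model, x) - t) ** 2
        assert after < before

    def test_target_equal_to_output_only_momentum_moves(self):
        model = init_model(NetworkConfig(seed=2, momentum=0.15))
        x = np.full(7, 0.5)
        t = forward(model, x)
        w1_before = model.w1.copy()
        state = {"w1": np.full_like(model.w1, 0.01)}
        backprop_step(model, x, t, state)
        # zero error gradient, so the step is alpha * previous delta
        np.testing.assert_allclose(model.w1 - w1_before, 0.15 * 0.01, atol=1e-12)

    def test_invalid_target_rejected(self):
        model = init_model(NetworkConfig(seed=0))
        with pytest.raises(ValueError):
            backprop_step(model, np.full(7, 0.5), 1.5)


class TestTrain:
    def test_xor_style_toy_is_learnable(self):
        """An XOR pattern padded to 7 inputs trains to MSE < 0.01."""
        rows, targets = [], []
        for a in (0.0, 1.0):
            for b in (0.0, 1.0):
                rows.append([a, b, 0.5, 0.5, 0.5, 0.5, 0.5])
                targets.append(float(int(a) ^ int(b)))
        cfg = NetworkConfig(learning_rate=0.3, momentum=0.9, epochs=5000, seed=2)
        model = train(_table(np.array(rows), targets), cfg)
        assert model.training_mse_history[-1] < 0.01

    def test_seeded_training_bit_reproducible(self):
        rng = np.random.default_rng(4)
        tab = _table(rng.uniform(size=(30, 7)), rng.uniform(size=30))
        cfg = NetworkConfig(epochs=20, seed=9)
        a = train(tab, cfg)
        b = train(tab, cfg)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)
        assert a.training_mse_history == b.training_mse_history

    def test_linear_problem_mse_trends_down(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(50, 7))
        t = np.clip(0.2 + 0.6 * X[:, 0], 0, 1)
        cfg = NetworkConfig(learning_rate=0.05, epochs=300, seed=1)
        model = train(_table(X, t), cfg)
        hist = np.array(model.training_mse_history)
        assert hist[-100:].mean() < hist[:100].mean()
        # last stretch non-increasing on average
        assert np.polyfit(np.arange(100), hist[-100:], 1)[0] <= 1e-6

    def test_batch_mode_runs_and_descends(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(40, 7))
        t = np.clip(0.3 + 0.4 * X[:, 1], 0, 1)
        cfg = NetworkConfig(learning_rate=0.5, epochs=500, seed=1, batch=True)
        model = train(_table(X, t), cfg)
        hist = model.training_mse_history
        assert hist[-1] < hist[0]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            train(_table(np.empty((0, 7)), []), NetworkConfig(epochs=1))


class TestPredictIndex:
    def test_index_is_output_times_hundred(self):
        model = init_model(NetworkConfig(seed=0))
        tab = _table(np.full((3, 7), 0.5), [0.0, 0.0, 0.0])
        expected = 100.0 * forward(model, np.full(7, 0.5))
        np.testing.assert_allclose(predict_index(model, tab), expected)

    def test_index_strictly_inside_scale(self):
        model = init_model(NetworkConfig(seed=1, init_scale=5.0))
        rng = np.random.default_rng(2)
        tab = _table(rng.uniform(size=(20, 7)), np.zeros(20))
        idx = predict_index(model, tab)
        assert np.all((idx > 0.0) & (idx < 100.0))

    def test_normalization_applied_from_model_bounds(self):
        bounds = NormBounds(bounds={c: (0.0, 200.0) for c in INPUT_COLUMNS})
        model = init_model(NetworkConfig(seed=3), norm_bounds=bounds)
        raw = _table(np.full((1, 7), 100.0), [0.0])  # normalizes to 0.5
        expected = 100.0 * forward(model, np.full(7, 0.5))
        assert predict_index(model, raw)[0] == pytest.approx(expected, abs=1e-12)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        bounds = NormBounds(bounds={c: (0.0, 1.0) for c in INPUT_COLUMNS})
        rng = np.random.default_rng(0)
        tab = _table(rng.uniform(size=(10, 7)), rng.uniform(size=10))
        model = train(tab, NetworkConfig(epochs=5, seed=11), bounds)
        path = tmp_path / "model.json"
        model_to_json(model, path)
        loaded = model_from_json(path)
        np.testing.assert_array_equal(loaded.w1, model.w1)
        np.testing.assert_array_equal(loaded.b2, model.b2)
        assert loaded.config == model.config
        assert loaded.norm_bounds == model.norm_bounds
        x = rng.uniform(size=7)
        assert forward(loaded, x) == forward(model, x)
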