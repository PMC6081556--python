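"""MLP classifier: forward pass, backprop correctness, training behavior."""

import numpy as np
import pytest

from emgkit import (
    backprop_step,
    classification_error,
    classify,
    forward,
    init_model,
    train,
)
from emgkit.mlp import MlpModel, forward_batch, gradients


def _one_hot(idx, n):
    t = np.zeros(n)
    t[idx] = 1.0
    return t


def numerical_gradients(model, x, target, h=1e-6):
    """Central-difference oracle for dL/dw on every weight entry."""

    def loss():
        _, y = forward(model, x)
        return 0.5 * float(np.sum((y - np.asarray(target)) ** 2))

    grads = []
    for w in model.weights:
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = w[idx]
            w[idx] = orig + h
            up = loss()
            w[idx] = orig - h
            down = loss()
            w[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads.append(g)
    return grads


class TestInitAndForward:
    def test_same_seed_identical_weights(self):
        a = init_model([3, 4, 2], seed=9)
        b = init_model([3, 4, 2], seed=9)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        assert all(np.all((w >= -0.5) & (w <= 0.5)) for w in a.weights)

    def test_paper_architecture_shapes(self):
        """Six input channels, eight hidden neurons, nine gesture outputs."""
        model = init_model([6, 8, 9], seed=0)
        assert model.weights[0].shape == (8, 7)  # 6 inputs + bias
        assert model.weights[1].shape == (9, 9)  # 8 hidden + bias

    def test_zero_weights_give_half_outputs(self):
        model = init_model([3, 2], seed=0)
        model.weights = [np.zeros_like(w) for w in model.weights]
        _, y = forward(model, [5.0, -1.0, 0.3])
        np.testing.assert_allclose(y, 0.5)
        assert classify(model, [1.0, 2.0, 3.0]) == 0  # tie -> lowest index

    def test_sigmoid_asymptote_and_midpoint(self):
        model = MlpModel([1, 1], [np.array([[1.0, 0.0]])])
        _, y = forward(model, [0.0])
        assert y[0] == pytest.approx(0.5)
        model = MlpModel([1, 1], [np.array([[1000.0, 0.0]])])
        _, y = forward(model, [1.0])
        assert y[0] == pytest.approx(1.0)

    def test_outputs_strictly_bounded(self):
        model = init_model([4, 6, 3], seed=2)
        rng = np.random.default_rng(0)
        out = forward_batch(model, rng.normal(scale=50.0, size=(100, 4)))
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_dimension_mismatch_raises(self):
        model = init_model([3, 2], seed=0)
        with pytest.raises(ValueError):
            forward(model, [1.0, 2.0])
        with pytest.raises(ValueError):
            forward(model, [np.nan, 1.0, 2.0])

    def test_bad_layer_specs_raise(self):
        with pytest.raises(ValueError):
            init_model([5], seed=0)
        with pytest.raises(ValueError):
            init_model([3, 0, 2], seed=0)


class TestBackprop:
    def test_zero_learning_rate_leaves_model_unchanged(self):
        model = init_model([3, 4, 2], seed=1)
        before = [w.copy() for w in model.weights]
        backprop_step(model, [0.2, 0.5, 0.9], _one_hot(1, 2), learning_rate=0.0)
        for w, b in zip(model.weights, before):
            assert np.array_equal(w, b)

    @pytest.mark.parametrize("sizes", [[3, 4, 2], [2, 2], [4, 5, 3, 2]])
    def test_gradients_match_numerical_oracle(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        model = init_model(sizes, seed=int(rng.integers(1000)))
        x = rng.uniform(0, 1, sizes[0])
        target = _one_hot(int(rng.integers(sizes[-1])), sizes[-1])
        analytic, _ = gradients(model, x, target)
        numeric = numerical_gradients(model, x, target)
        for a, n in zip(analytic, numeric):
            denom = max(np.linalg.norm(a) + np.linalg.norm(n), 1e-8)
            assert np.linalg.norm(a - n) / denom < 1e-6

    def test_no_bias_variant_gradients(self):
        model = init_model([3, 3, 2], seed=4, bias=False)
        x = np.array([0.1, 0.7, 0.4])
        target = _one_hot(0, 2)
        analytic, _ = gradients(model, x, target)
        numeric = numerical_gradients(model, x, target)
        for a, n in zip(analytic, numeric):
            assert np.allclose(a, n, atol=1e-8)

    def test_single_step_descends(self):
        """One small update strictly decreases that sample's squared error."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            model = init_model([3, 4, 2], seed=trial)
            x = rng.uniform(0, 1, 3)
            target = _one_hot(int(rng.integers(2)), 2)
            loss_before = backprop_step(model, x, target, learning_rate=1e-4)
            _, loss_after = gradients(model, x, target)
            assert loss_after < loss_before


class TestTraining:
    def test_separable_two_gestures_reach_zero_train_error(self, two_gesture_model):
        fitted, run, train_xy, test_xy = two_gesture_model
        assert classification_error(fitted, train_xy) == 0.0
        assert classification_error(fitted, test_xy) == 0.0

    def test_single_epoch_when_capped(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(20, 3))
        y = (x[:, 0] > 0.5).astype(int)
        model = init_model([3, 2], seed=0)
        run, _ = train(model, (x, y), (x, y), max_epochs=1, patience=0, seed=0)
        assert run.stopped_at == 1
        assert len(run.epoch_log) == 1

    def test_missing_training_class_raises(self):
        x = np.random.default_rng(0).uniform(size=(10, 2))
        y_train = np.zeros(10, int)
        y_test = np.array([0, 1] * 5)
        model = init_model([2, 1], seed=0)
        with pytest.raises(ValueError, match=r"\[1\]"):
            train(model, (x, y_train), (x, y_test), max_epochs=1, seed=0)

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(30, 3))
        y = (x[:, 1] > 0.5).astype(int)

        def go():
            model = init_model([3, 4, 2], seed=7)
            run, fitted = train(
                model, (x, y), (x, y), max_epochs=30, patience=5, seed=7
            )
            return run.epoch_log, [w.copy() for w in fitted.weights]

        log_a, w_a = go()
        log_b, w_b = go()
        assert log_a == log_b
        for a, b in zip(w_a, w_b):
            assert np.array_equal(a, b)

    def test_error_log_bounds_and_best_restoration(self, two_gesture_model):
        fitted, run, _, test_xy = two_gesture_model
        assert all(0.0 <= e <= 1.0 for pair in run.epoch_log for e in pair)
        best_test = min(run.test_errors)
        assert classification_error(fitted, test_xy) == pytest.approx(best_test)

    def test_classification_error_arithmetic(self):
        model = init_model([2, 2], seed=0)
        model.weights = [np.zeros_like(model.weights[0])]
        model.classes = np.array([0, 1])
        x = np.zeros((8, 2))
        y = np.array([0] * 7 + [1])  # zero-weight model always answers 0
        assert classification_error(model, (x, y)) == pytest.approx(0.125)
        with pytest.raises(ValueError):
            classification_error(model, (np.empty((0, 2)), np.empty(0, int)))
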