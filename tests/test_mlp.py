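"""MLP forecaster: shapes, forward pass, and the four trainers."""

import numpy as np
import pytest

from resicast import gen_ar, make_lag_matrix
from resicast.mlp import (
    TRAINERS,
    MLPConfig,
    TrainOptions,
    forward,
    init_model,
    train,
)
from resicast.series import SupervisedWindowSet


def _split_windows(series, lags, train_frac=0.8):
    w = make_lag_matrix(series, lags)
    k = int(w.n_rows * train_frac)
    tr = SupervisedWindowSet(w.inputs[:k], w.targets[:k], w.lags, w.target_indices[:k])
    va = SupervisedWindowSet(w.inputs[k:], w.targets[k:], w.lags, w.target_indices[k:])
    return tr, va


class TestInit:
    def test_seeded_determinism(self):
        cfg = MLPConfig(n_inputs=3, n_hidden=2, seed=42)
        a, b = init_model(cfg), init_model(cfg)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)
        assert a.b2 == b.b2

    def test_shapes(self):
        m = init_model(MLPConfig(n_inputs=3, n_hidden=2))
        assert m.w1.shape == (2, 3) and m.b1.shape == (2,) and m.w2.shape == (2,)
        assert m.n_params == 2 * 3 + 2 + 2 + 1

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=1, n_hidden=0)
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=1, n_hidden=2, trainer="adam")


class TestForward:
    def test_zero_weights_give_bias(self):
        m = init_model(MLPConfig(n_inputs=2, n_hidden=3, seed=0))
        m.w1[:] = 0.0
        m.b1[:] = 0.0
        m.w2[:] = 0.0
        m.b2 = 0.7
        np.testing.assert_allclose(forward(m, np.zeros((4, 2))), 0.7)

    def test_hand_computed_single_unit(self):
        m = init_model(MLPConfig(n_inputs=1, n_hidden=1, seed=0))
        m.w1[:] = 2.0
        m.b1[:] = -1.0
        m.w2[:] = 3.0
        m.b2 = 0.5
        x = 0.8
        expected = 3.0 / (1.0 + np.exp(-(2.0 * x - 1.0))) + 0.5
        assert forward(m, [[x]])[0] == pytest.approx(expected, abs=1e-12)

    def test_width_mismatch(self):
        m = init_model(MLPConfig(n_inputs=2, n_hidden=1))
        with pytest.raises(ValueError):
            forward(m, np.zeros((3, 4)))

    def test_duplicate_rows_duplicate_outputs(self):
        m = init_model(MLPConfig(n_inputs=2, n_hidden=3, seed=1))
        out = forward(m, np.array([[0.3, 0.4], [0.3, 0.4]]))
        assert out[0] == out[1]


@pytest.mark.parametrize("trainer", TRAINERS)
class TestTrainers:
    def test_constant_target_reaches_zero_error(self, trainer, fast_opts):
        x = np.full(80, 3.0) + 0.0
        w = make_lag_matrix(x, 1)
        tr = SupervisedWindowSet(w.inputs[:60], w.targets[:60], w.lags, w.target_indices[:60])
        va = SupervisedWindowSet(w.inputs[60:], w.targets[60:], w.lags, w.target_indices[60:])
        m = train(init_model(MLPConfig(1, 1, trainer, seed=3)), tr, va, fast_opts)
        final = float(np.mean((forward(m, tr.inputs) - tr.targets) ** 2))
        # target level is 3.0, so 1e-2 is a relative error below 2%
        assert final < 1e-2

    def test_training_error_not_worse_than_initial(self, trainer, fast_opts):
        series = gen_ar(300, (0.8,), 1.0, seed=11)
        tr, va = _split_windows(series, 2)
        m0 = init_model(MLPConfig(2, 3, trainer, seed=7))
        initial = float(np.mean((forward(m0, tr.inputs) - tr.targets) ** 2))
        m = train(m0, tr, va, fast_opts)
        final = float(np.mean((forward(m, tr.inputs) - tr.targets) ** 2))
        assert final <= initial + 1e-12

    def test_returned_val_error_is_log_minimum(self, trainer, fast_opts):
        series = gen_ar(300, (0.8,), 1.0, seed=5)
        tr, va = _split_windows(series, 1)
        m = train(init_model(MLPConfig(1, 2, trainer, seed=2)), tr, va, fast_opts)
        val = float(np.mean((forward(m, va.inputs) - va.targets) ** 2))
        logged_min = min(entry[2] for entry in m.training_log)
        assert val == pytest.approx(logged_min, rel=1e-9)

    def test_seeded_runs_reproducible(self, trainer, fast_opts):
        series = gen_ar(200, (0.6,), 1.0, seed=9)
        tr, va = _split_windows(series, 2)
        cfg = MLPConfig(2, 2, trainer, seed=13)
        m1 = train(init_model(cfg), tr, va, fast_opts)
        m2 = train(init_model(cfg), tr, va, fast_opts)
        np.testing.assert_array_equal(m1.get_params(), m2.get_params())

    def test_ar1_validation_mse_near_innovation_variance(self, trainer, fast_opts):
        # AR(1) phi=0.8, unit innovations: the optimal one-lag predictor
        # leaves validation MSE ~ 1; the trained net must come close
        series = gen_ar(500, (0.8,), 1.0, seed=3)
        tr, va = _split_windows(series, 1)
        m = train(init_model(MLPConfig(1, 2, trainer, seed=1)), tr, va, fast_opts)
        val_mse = float(np.mean((forward(m, va.inputs) - va.targets) ** 2))
        assert val_mse <= 1.2


class TestLMAgainstLeastSquares:
    def test_linear_network_matches_ols(self):
        # with identity activations the network is an affine map; LM must
        # reach the least-squares predictions
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 2))
        beta = np.array([1.5, -0.7])
        y = X @ beta + 0.3 + 0.05 * rng.normal(size=120)
        w = SupervisedWindowSet(X, y, (2, 1), np.arange(2, 122))
        cfg = MLPConfig(2, 2, "lm", hidden_activation="identity", seed=4)
        opts = TrainOptions(max_iterations=300, generalization_loss_pct=1e6, min_progress=1e-15)
        m = train(init_model(cfg), w, w, opts)
        A = np.column_stack([X, np.ones(len(y))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(forward(m, X), A @ coef, atol=1e-6)


class TestSerialization:
    def test_round_trip(self, fast_opts):
        from resicast.mlp import MLPModel

        series = gen_ar(150, (0.5,), 1.0, seed=2)
        tr, va = _split_windows(series, 2)
        m = train(init_model(MLPConfig(2, 2, "rprop", seed=6)), tr, va, fast_opts)
        m2 = MLPModel.from_dict(m.to_dict())
        np.testing.assert_array_equal(m.get_params(), m2.get_params())
        np.testing.assert_array_equal(forward(m, tr.inputs), forward(m2, tr.inputs))
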