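import numpy as np
import pytest
from scipy.special import expit

from wbam.narx import (
    NarxConfig,
    NarxModel,
    Scaler,
    TrialSet,
    assemble_regressors,
    forward,
    partition_trials,
    predict_closed_loop,
    predict_open_loop,
    scg_train,
)
from wbam.narx import _loss, _loss_grad


def _tiny_config(**kw):
    base = dict(
        n_inputs=2, n_outputs=1, n_hidden=3, input_taps=(0, 1), output_taps=(1,),
        max_epochs=50, seed=0,
    )
    base.update(kw)
    return NarxConfig(**base)


def _identity_scaler(n):
    return Scaler(lo=-np.ones(n), hi=np.ones(n))


class TestAssembleRegressors:
    def test_hand_construction(self):
        cfg = NarxConfig(n_inputs=1, n_outputs=1, n_hidden=1, input_taps=(0,), output_taps=(1,))
        u = np.array([[10.0], [11.0], [12.0]])
        y = np.array([[0.0], [1.0], [2.0]])
        X, T = assemble_regressors(u, y, cfg)
        assert X.shape == (2, 2)
        np.testing.assert_allclose(X[0], [11.0, 0.0])  # u(1), y(0)
        np.testing.assert_allclose(X[1], [12.0, 1.0])
        np.testing.assert_allclose(T[:, 0], [1.0, 2.0])

    def test_default_regressor_dimension(self):
        assert NarxConfig().regressor_dim == 9 * 30 + 8 * 15 == 390

    def test_constant_sequences_give_identical_rows(self):
        cfg = _tiny_config()
        X, _ = assemble_regressors(np.ones((9, 2)), np.ones((9, 1)), cfg)
        assert np.all(X == X[0])

    def test_short_sequence_rejected(self):
        cfg = NarxConfig()
        with pytest.raises(ValueError):
            assemble_regressors(np.ones((8, 30)), np.ones((8, 15)), cfg)


class TestForward:
    def test_zero_weights_give_unscaled_zero(self):
        cfg = _tiny_config()
        out_sc = Scaler(lo=np.array([10.0]), hi=np.array([20.0]))
        m = NarxModel.initialize(cfg, _identity_scaler(2), out_sc)
        m.unpack(np.zeros(m.n_params))
        y = forward(m, np.zeros(cfg.regressor_dim))
        assert y[0] == pytest.approx(15.0)  # midpoint of [10, 20]

    def test_one_hidden_unit_hand_calculation(self):
        cfg = NarxConfig(n_inputs=1, n_outputs=1, n_hidden=1, input_taps=(0,), output_taps=(1,))
        m = NarxModel.initialize(cfg, _identity_scaler(1), _identity_scaler(1))
        m.W1 = np.array([[0.5, -0.25]])
        m.b1 = np.array([0.1])
        m.W2 = np.array([[2.0]])
        m.b2 = np.array([-0.3])
        x = np.array([0.8, 0.4])  # already in [-1,1] space (identity scalers)
        expected = 2.0 * expit(0.5 * 0.8 - 0.25 * 0.4 + 0.1) - 0.3
        assert forward(m, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        cfg = _tiny_config()
        m = NarxModel.initialize(cfg, _identity_scaler(2), _identity_scaler(1))
        with pytest.raises(ValueError):
            forward(m, np.zeros(cfg.regressor_dim + 1))

    def test_saturating_inputs_stay_finite(self):
        cfg = _tiny_config()
        m = NarxModel.initialize(cfg, _identity_scaler(2), _identity_scaler(1))
        assert np.isfinite(forward(m, np.full(cfg.regressor_dim, 1e6))).all()


class TestGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_backprop_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        cfg = NarxConfig(
            n_inputs=rng.integers(1, 4), n_outputs=rng.integers(1, 3),
            n_hidden=rng.integers(1, 5), input_taps=(0, 1), output_taps=(1, 2),
            seed=seed,
        )
        u = rng.normal(size=(30, cfg.n_inputs))
        y = rng.normal(size=(30, cfg.n_outputs))
        m = NarxModel.initialize(cfg, Scaler.fit([u]), Scaler.fit([y]))
        X, T = assemble_regressors(
            m.in_scaler.transform(u), m.out_scaler.transform(y), cfg
        )
        w = m.pack() + 0.05 * rng.standard_normal(m.n_params)
        _, g = _loss_grad(m, w, X, T)
        eps = 1e-6
        gfd = np.empty_like(g)
        for i in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            gfd[i] = (_loss(m, wp, X, T) - _loss(m, wm, X, T)) / (2 * eps)
        # denominator floored at 1e-3 of the gradient scale so components at
        # the finite-difference noise floor don't dominate the relative error
        rel = np.abs(g - gfd) / np.maximum(np.abs(gfd), 1e-3 * np.abs(gfd).max())
        assert rel.max() < 1e-6


class TestScgTraining:
    def test_linear_network_reaches_least_squares_solution(self, rng):
        """With identity activation the training problem is quadratic; SCG
        must land on the normal-equations solution."""
        cfg = NarxConfig(
            n_inputs=3, n_outputs=2, n_hidden=4, input_taps=(0, 1), output_taps=(1,),
            activation="identity", max_epochs=600, patience=10**9, seed=5,
        )
        A = rng.normal(size=(2, 3))
        u = rng.normal(size=(300, 3))
        y = u @ A.T
        ts = TrialSet(inputs=[u, u.copy()], targets=[y, y.copy()])
        ts.partition = np.array(["train", "train"])
        model, report = scg_train(ts, cfg)
        # oracle: least squares in the same scaled regressor space
        us, ys = model.in_scaler.transform(u), model.out_scaler.transform(y)
        X, T = assemble_regressors(us, ys, cfg)
        Xa = np.hstack([X, np.ones((len(X), 1))])
        coef, *_ = np.linalg.lstsq(Xa, T, rcond=None)
        pred_ls = Xa @ coef
        Yhat = predict_open_loop(model, u, y)
        pred_net = model.out_scaler.transform(Yhat[cfg.max_lag :])
        assert np.abs(pred_net - pred_ls).max() < 1e-6

    def test_training_error_monotone_nonincreasing(self, rng):
        cfg = _tiny_config(max_epochs=60, patience=10**9)
        u = rng.normal(size=(120, 2))
        y = np.stack([np.sin(np.arange(120) * 0.2)], axis=1)
        ts = TrialSet(inputs=[u] * 2, targets=[y] * 2)
        ts.partition = np.array(["train", "train"])
        _, report = scg_train(ts, cfg)
        diffs = np.diff(report.train_mse)
        assert diffs.max() <= 1e-12

    def test_linear_mapping_recovered_below_one_percent_rmse(self, rng):
        """Noise-free y(t) = A u(t): open-loop RMSE under 1% of target SD."""
        A = rng.normal(size=(2, 3))
        cfg = NarxConfig(
            n_inputs=3, n_outputs=2, n_hidden=10, input_taps=(0,), output_taps=(1,),
            max_epochs=500, patience=10**9, seed=2,
        )
        trials_u = [rng.normal(size=(150, 3)) for _ in range(4)]
        trials_y = [u @ A.T for u in trials_u]
        ts = TrialSet(inputs=trials_u, targets=trials_y)
        ts.partition = np.array(["train", "train", "train", "val"])
        model, _ = scg_train(ts, cfg)
        u, y = trials_u[-1], trials_y[-1]
        yhat = predict_open_loop(model, u, y)
        rmse = np.sqrt(np.mean((yhat[1:] - y[1:]) ** 2))
        assert rmse < 0.01 * y.std()

    def test_same_seed_reproduces_training_bitwise(self, rng):
        cfg = _tiny_config(max_epochs=30)
        u = rng.normal(size=(100, 2))
        y = rng.normal(size=(100, 1)).cumsum(axis=0)
        ts1 = TrialSet(inputs=[u] * 3, targets=[y] * 3)
        ts2 = TrialSet(inputs=[u.copy()] * 3, targets=[y.copy()] * 3)
        for ts in (ts1, ts2):
            ts.partition = np.array(["train", "val", "test"])
        m1, r1 = scg_train(ts1, cfg)
        m2, r2 = scg_train(ts2, cfg)
        assert np.array_equal(m1.pack(), m2.pack())
        assert r1.train_mse == r2.train_mse
        assert r1.best_epoch == r2.best_epoch


class TestClosedLoop:
    def _input_only_model(self):
        """Weights wired so the network ignores its output taps."""
        cfg = NarxConfig(
            n_inputs=1, n_outputs=1, n_hidden=2, input_taps=(0,), output_taps=(1,),
            activation="identity",
        )
        m = NarxModel.initialize(cfg, _identity_scaler(1), _identity_scaler(1))
        m.W1 = np.array([[1.0, 0.0], [0.0, 0.0]])  # hidden sees only u(t)
        m.b1 = np.zeros(2)
        m.W2 = np.array([[1.0, 0.0]])
        m.b2 = np.zeros(1)
        return m

    def test_closed_equals_open_when_output_taps_unused(self, rng):
        m = self._input_only_model()
        u = rng.normal(size=(40, 1))
        y = u.copy()  # the wired model computes yhat = u
        open_ = predict_open_loop(m, u, y)
        closed = predict_closed_loop(m, u, y_init=y)
        np.testing.assert_allclose(open_[1:], closed[1:], atol=1e-12)

    def test_minimal_length_input(self, rng):
        m = self._input_only_model()
        u = rng.normal(size=(2, 1))  # max lag + 1 frames
        out = predict_closed_loop(m, u, y_init=np.zeros((1, 1)))
        assert out.shape == (2, 1)

    def test_closed_loop_tracks_open_loop_on_converged_toy(self, rng):
        """On a stable autoregressive toy system the closed-loop rollout
        stays within 10x the open-loop RMSE."""
        n = 400
        u = rng.normal(size=(n, 1))
        y = np.zeros((n, 1))
        for t in range(1, n):
            y[t] = 0.8 * y[t - 1] + 0.5 * u[t]
        cfg = NarxConfig(
            n_inputs=1, n_outputs=1, n_hidden=6, input_taps=(0,), output_taps=(1,),
            max_epochs=400, patience=10**9, seed=1,
        )
        ts = TrialSet(inputs=[u] * 3, targets=[y] * 3)
        ts.partition = np.array(["train", "train", "val"])
        model, _ = scg_train(ts, cfg)
        yo = predict_open_loop(model, u, y)
        yc = predict_closed_loop(model, u, y_init=y)
        rmse_o = np.sqrt(np.mean((yo[1:] - y[1:]) ** 2))
        rmse_c = np.sqrt(np.mean((yc[1:] - y[1:]) ** 2))
        assert rmse_c < 10 * rmse_o

    def test_missing_initialization_uses_zero_history(self, rng):
        m = self._input_only_model()
        u = rng.normal(size=(10, 1))
        out = predict_closed_loop(m, u)  # no y_init: zero history
        np.testing.assert_allclose(out[1:], u[1:], atol=1e-12)


class TestScalerAndPartition:
    def test_scaler_roundtrip(self, rng):
        x = rng.normal(size=(50, 4)) * 10 + 3
        sc = Scaler.fit([x])
        np.testing.assert_allclose(sc.inverse(sc.transform(x)), x, atol=1e-12)
        assert sc.transform(x).min() == pytest.approx(-1.0)
        assert sc.transform(x).max() == pytest.approx(1.0)

    def test_degenerate_channel_floored(self):
        sc = Scaler.fit([np.full((10, 1), 7.0)])
        assert sc.hi[0] > sc.lo[0]

    @pytest.mark.parametrize(
        "n,expected", [(200, (140, 30, 30)), (3, (1, 1, 1)), (60, (42, 9, 9))]
    )
    def test_partition_counts(self, n, expected):
        ts = TrialSet(inputs=[np.ones((9, 1))] * n, targets=[np.ones((9, 1))] * n)
        partition_trials(ts, seed=0)
        counts = tuple(int(np.sum(ts.partition == p)) for p in ("train", "val", "test"))
        assert counts == expected

    def test_partition_reproducible_and_small_n_rejected(self):
        ts1 = TrialSet(inputs=[np.ones((9, 1))] * 10, targets=[np.ones((9, 1))] * 10)
        ts2 = TrialSet(inputs=[np.ones((9, 1))] * 10, targets=[np.ones((9, 1))] * 10)
        partition_trials(ts1, seed=5)
        partition_trials(ts2, seed=5)
        assert np.array_equal(ts1.partition, ts2.partition)
        bad = TrialSet(inputs=[np.ones((9, 1))] * 2, targets=[np.ones((9, 1))] * 2)
        with pytest.raises(ValueError):
            partition_trials(bad)


class TestConfigValidation:
    def test_output_tap_zero_rejected(self):
        with pytest.raises(ValueError):
            NarxConfig(output_taps=(0, 1))

    def test_empty_taps_rejected(self):
        with pytest.raises(ValueError):
            NarxConfig(input_taps=())
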