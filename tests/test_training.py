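"""Training: task geometry, the learning rule's gradient, determinism,
descent behaviour, and the exponential learning-speed fit."""

import numpy as np
import pytest

import synbias as sb
from synbias.network import init_nonsynergy, make_input
from synbias.training import (
    TrainConfig,
    _exp_model,
    fit_learning_speed,
    train,
    train_step,
)


class TestTaskTargets:
    def test_standard_twelve_target_task(self):
        tasks = sb.make_task_targets(12, 1.0)
        assert tasks.n_targets == 12
        assert tasks.spacing == pytest.approx(30.0)
        np.testing.assert_allclose(
            np.linalg.norm(tasks.targets, axis=1), 1.0, atol=1e-12
        )

    def test_dataset_grid(self):
        tasks = sb.make_task_targets(120)
        assert tasks.spacing == pytest.approx(3.0)

    def test_single_target(self):
        tasks = sb.make_task_targets(1, 0.8)
        np.testing.assert_allclose(tasks.targets, [[0.8, 0.0]], atol=1e-12)


class TestTrainStep:
    def test_zero_error_zero_decay_leaves_weights(self):
        # scalar network where the target solving e = 0 is available in
        # closed form: T0 = d z (w0 tau0 + w2 b0 + w3 b1) + t0, tau1 = 0
        d, t0, z = 1.5, 0.2, 0.8
        plant = sb.Plant(
            D=np.array([[d, 0.0], [0.0, 1.0]]),
            t_pl=np.array([t0, 0.0]),
            validate=False,
        )
        w = np.array([[0.3, 0.0, 0.2, 0.05]])
        tau0 = (d * z * (0.2 + 0.05) + t0) / (1.0 - d * z * 0.3)
        state = sb.NetworkState(
            w_inp=w.copy(), z=np.array([[z], [0.0]]), bias=np.array([1.0, 1.0])
        )
        cfg = TrainConfig(alpha=0.5, beta=0.0, n_trials=1)
        _, err = train_step(state, plant, np.array([tau0, 0.0]), cfg)
        assert err == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(state.w_inp, w, atol=1e-12)

    def test_pure_decay_shrinks_by_exact_factor(self, tiny_plant):
        state = init_nonsynergy(4, n_m1=10, seed=1)
        w0 = state.w_inp.copy()
        cfg = TrainConfig(alpha=0.0, beta=1e-3, n_trials=1)
        train_step(state, tiny_plant, np.array([1.0, 0.0]), cfg)
        np.testing.assert_allclose(state.w_inp, w0 * (1 - 1e-3), rtol=1e-15)

    def test_scalar_network_gradient_matches_hand_derivation(self):
        # 1 muscle (ignore feasibility), 1 neuron, scalar everything:
        # pre = z * w . x, a = relu(pre), T = d*a + t0, J = 1/2 |tau - T|^2
        # dJ/dw_k = -(tau - T) * d * z * x_k   (when pre > 0)
        d, t0, z = 1.5, 0.2, 0.8
        plant = sb.Plant(
            D=np.array([[d, 0.0], [0.0, 1.0]]),
            t_pl=np.array([t0, 0.0]),
            validate=False,
        )
        w = np.array([[0.3, -0.1, 0.2, 0.05]])
        state = sb.NetworkState(
            w_inp=w.copy(),
            z=np.array([[z], [0.0]]),
            bias=np.array([1.0, 1.0]),
        )
        tau = np.array([1.0, 0.0])
        x = np.concatenate([tau, state.bias])
        pre = z * float(w[0] @ x)
        assert pre > 0
        a = pre
        T = np.array([d * a + t0, 0.0])
        e = tau - T
        grad = -(d * e[0]) * z * x  # row gradient for the single neuron
        alpha, beta = 0.01, 1e-4
        expected = w - alpha * grad - beta * w
        cfg = TrainConfig(alpha=alpha, beta=beta, n_trials=1)
        _, err = train_step(state, plant, tau, cfg)
        np.testing.assert_allclose(state.w_inp, expected, atol=1e-14)
        assert err == pytest.approx(np.linalg.norm(e), abs=1e-14)

    def test_rectifier_subgradient_blocks_inactive_units(self, tiny_plant):
        state = sb.NetworkState(
            w_inp=-np.ones((5, 4)),
            z=np.abs(np.random.default_rng(2).normal(size=(4, 5))),
            bias=np.array([1.0, 1.0]),
        )
        w0 = state.w_inp.copy()
        cfg = TrainConfig(alpha=0.1, beta=0.0, n_trials=1)
        train_step(state, tiny_plant, np.array([1.0, 1.0]), cfg)
        # all pre-activations negative -> zero gradient -> no update
        np.testing.assert_array_equal(state.w_inp, w0)


class TestTrain:
    def test_zero_trials_is_identity(self, tiny_plant):
        state = init_nonsynergy(4, n_m1=10, seed=0)
        w0 = state.w_inp.copy()
        tasks = sb.make_task_targets(12)
        state, curve = train(state, tiny_plant, tasks, TrainConfig(n_trials=0))
        assert len(curve) == 0
        np.testing.assert_array_equal(state.w_inp, w0)

    def test_bit_reproducible(self, base_plant):
        tasks = sb.make_task_targets(12)
        cfg = TrainConfig(n_trials=500, seed=42)
        s1, c1 = train(init_nonsynergy(22, n_m1=200, seed=3), base_plant, tasks, cfg)
        s2, c2 = train(init_nonsynergy(22, n_m1=200, seed=3), base_plant, tasks, cfg)
        assert np.array_equal(c1.errors, c2.errors)
        assert np.array_equal(s1.w_inp, s2.w_inp)

    def test_frozen_weights_error_statistics_flat(self, base_plant):
        tasks = sb.make_task_targets(12)
        cfg = TrainConfig(alpha=0.0, beta=0.0, n_trials=2000, seed=0)
        _, curve = train(init_nonsynergy(22, seed=1), base_plant, tasks, cfg)
        first = curve.errors[:1000].mean()
        last = curve.errors[-1000:].mean()
        assert last == pytest.approx(first, rel=0.05)

    def test_learning_decreases_error(self, base_plant):
        tasks = sb.make_task_targets(12)
        cfg = TrainConfig(n_trials=5000, seed=2)
        _, curve = train(init_nonsynergy(22, seed=2), base_plant, tasks, cfg)
        assert curve.errors[-100:].mean() < curve.errors[:100].mean()

    def test_matches_stepwise_reference(self, base_plant):
        """The compiled loop and the numpy reference step agree."""
        tasks = sb.make_task_targets(12)
        cfg = TrainConfig(n_trials=200, seed=9)
        fast_state, curve = train(
            init_nonsynergy(22, n_m1=100, seed=7), base_plant, tasks, cfg
        )
        slow_state = init_nonsynergy(22, n_m1=100, seed=7)
        rng = np.random.default_rng(cfg.seed)
        idx = rng.integers(0, tasks.n_targets, size=cfg.n_trials)
        errs = []
        for i in idx:
            slow_state, err = train_step(
                slow_state, base_plant, tasks.targets[i], cfg
            )
            errs.append(err)
        np.testing.assert_allclose(curve.errors, errs, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(
            fast_state.w_inp, slow_state.w_inp, rtol=1e-9, atol=1e-14
        )

    def test_monotone_descent_single_target_small_alpha(self):
        # 2-muscle plant, single fixed target, no decay: plain gradient
        # descent decreases the error monotonically for small alpha
        plant = sb.Plant(
            D=np.array([[1.0, -1.0], [0.5, 0.5]]),
            t_pl=np.zeros(2),
            validate=False,
        )
        state = init_nonsynergy(2, n_m1=10, seed=0, sigma_init=0.2)
        cfg = TrainConfig(alpha=0.01, beta=0.0, n_trials=1)
        target = np.array([0.5, 0.5])
        errs = []
        for _ in range(200):
            state, err = train_step(state, plant, target, cfg)
            errs.append(err)
        diffs = np.diff(errs)
        assert np.all(diffs <= 1e-12)


class TestFinalError:
    def test_constant_curve(self):
        curve = sb.LearningCurve(
            errors=np.full(500, 0.2), targets_drawn=np.zeros(500, dtype=int)
        )
        assert sb.final_error(curve) == pytest.approx(0.2)

    def test_full_window_is_overall_mean(self):
        e = np.arange(10.0)
        curve = sb.LearningCurve(errors=e, targets_drawn=np.zeros(10, dtype=int))
        assert sb.final_error(curve, window=10) == pytest.approx(e.mean())

    def test_two_trial_window(self):
        e = np.array([1.0, 1.0, 0.1, 0.3])
        curve = sb.LearningCurve(errors=e, targets_drawn=np.zeros(4, dtype=int))
        assert sb.final_error(curve, window=2) == pytest.approx(0.2)

    def test_empty_curve_rejected(self):
        curve = sb.LearningCurve(
            errors=np.empty(0), targets_drawn=np.empty(0, dtype=int)
        )
        with pytest.raises(ValueError):
            sb.final_error(curve)


class TestFitLearningSpeed:
    def test_noiseless_recovery(self):
        t = np.arange(25_000, dtype=float)
        e = _exp_model(t, 1.0, 0.002, 0.05)
        fit = fit_learning_speed(e)
        assert fit.v == pytest.approx(0.002, rel=1e-6)
        assert fit.gamma1 == pytest.approx(1.0, rel=1e-6)
        assert fit.gamma2 == pytest.approx(0.05, rel=1e-6)

    def test_constant_curve_degenerates_gracefully(self):
        fit = fit_learning_speed(np.full(1000, 0.3))
        assert fit.gamma1 * (1 - np.exp(-fit.v)) == pytest.approx(0.0, abs=1e-6)
        assert fit.gamma1 + fit.gamma2 == pytest.approx(0.3, abs=1e-6)

    def test_recovery_under_multiplicative_noise(self):
        t = np.arange(25_000, dtype=float)
        rel_errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            e = _exp_model(t, 1.0, 0.002, 0.05)
            e = e * (1.0 + 0.05 * rng.standard_normal(t.shape))
            fit = fit_learning_speed(e)
            rel_errors.append(abs(fit.v - 0.002) / 0.002)
        assert max(rel_errors) < 0.05

    def test_invariant_to_subsampling(self):
        t = np.arange(25_000, dtype=float)
        e = _exp_model(t, 0.8, 0.001, 0.04)
        v_full = fit_learning_speed(e).v
        v_sub = fit_learning_speed(e[::10]).v * 0.1  # rate per original trial
        assert v_sub == pytest.approx(v_full, rel=0.02)

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_learning_speed(np.array([1.0, 0.5]))
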