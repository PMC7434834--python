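"""Core network: initialization, dynamics, NLL, BPTT oracle, updates."""

import dataclasses

import numpy as np
import pytest

from sctrnnpb import (Gradients, ModelConfig, NetworkParameters,
                      apply_momentum_update, bptt_gradients, dataset_nll,
                      forward_step, init_parameters, load_checkpoint,
                      run_closed_loop, run_open_loop, save_checkpoint,
                      sequence_nll, stepwise_nll)
from sctrnnpb.model import initial_state


def _tiny_config(**kw):
    base = dict(n_input=3, n_mean=3, n_variance=3, n_context=3, n_pb=2,
                tau=4.0, bias_variance_k=1.0)
    base.update(kw)
    return ModelConfig(**base)


class TestInit:
    def test_weight_bounds_follow_source_layer_size(self):
        config = ModelConfig(bias_variance_k=10.0)
        params = init_parameters(config, 0, n_sequences=6)
        assert np.max(np.abs(params.W_input_to_context)) <= 1 / np.sqrt(10)
        for name in ("W_context_to_context", "W_pb_to_context",
                     "W_context_to_mean", "W_context_to_variance"):
            assert np.max(np.abs(getattr(params, name))) <= 1 / np.sqrt(100)
        assert np.max(np.abs(params.b_mean)) <= 1.0
        assert np.max(np.abs(params.b_variance)) <= 1.0
        assert np.array_equal(params.u0_pb, np.zeros((6, 2)))

    def test_context_bias_variance_matches_k(self):
        """Sample variance of N(0, 10) over 100 neurons lies inside the
        chi-square 99% band [4, 20]."""
        config = ModelConfig(bias_variance_k=10.0)
        samples = [init_parameters(config, seed).b_context.var(ddof=1)
                   for seed in range(5)]
        for s in samples:
            assert 4.0 < s < 20.0

    def test_degenerate_k_zero_gives_constant_biases(self):
        params = init_parameters(_tiny_config(bias_variance_k=0.0,
                                              bias_mean=0.25), 1)
        assert np.array_equal(params.b_context, np.full(3, 0.25))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(bias_variance_k=-1.0)

    def test_pure_function_of_seed(self):
        a = init_parameters(_tiny_config(), 42, n_sequences=3)
        b = init_parameters(_tiny_config(), 42, n_sequences=3)
        for f in dataclasses.fields(a):
            assert np.array_equal(getattr(a, f.name), getattr(b, f.name))


def _zero_params(config, n_sequences=1):
    params = init_parameters(config, 0, n_sequences=n_sequences)
    for f in dataclasses.fields(params):
        if f.name != "tau":
            getattr(params, f.name)[...] = 0.0
    return params


class TestForwardStep:
    def test_all_zero_network_outputs_unit_variance(self):
        config = _tiny_config()
        params = _zero_params(config)
        state = forward_step(params, initial_state(params, np.zeros(2)),
                             np.zeros(3))
        assert np.array_equal(state.c, np.zeros(3))
        assert np.array_equal(state.y, np.zeros(3))
        assert np.array_equal(state.v, np.ones(3))

    def test_leak_arithmetic_single_neuron(self):
        """tau=4, zero weights, b=4, u_prev=0: u = 4/4 + 0 = 1."""
        config = ModelConfig(n_input=1, n_mean=1, n_variance=1, n_context=1,
                             n_pb=1, tau=4.0, bias_variance_k=0.0)
        params = _zero_params(config)
        params.b_context[...] = 4.0
        state = forward_step(params, initial_state(params, np.zeros(1)),
                             np.zeros(1))
        assert state.u_context[0] == pytest.approx(1.0)
        assert state.c[0] == pytest.approx(np.tanh(1.0))

    def test_unit_tau_direct_drive(self):
        config = ModelConfig(n_input=1, n_mean=1, n_variance=1, n_context=1,
                             n_pb=1, tau=1.0, bias_variance_k=0.0)
        params = _zero_params(config)
        params.W_input_to_context[...] = 1.0
        state = forward_step(params, initial_state(params, np.zeros(1)),
                             np.array([0.5]))
        assert state.u_context[0] == pytest.approx(0.5)
        assert state.c[0] == pytest.approx(np.tanh(0.5))

    def test_pb_state_passes_through_unchanged(self):
        config = _tiny_config()
        params = init_parameters(config, 3)
        u0 = np.array([0.3, -0.7])
        state = initial_state(params, u0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = forward_step(params, state, rng.uniform(-0.5, 0.5, 3))
            assert np.array_equal(state.u_pb, u0)

    def test_non_finite_input_rejected(self):
        params = init_parameters(_tiny_config(), 0)
        with pytest.raises(ValueError):
            forward_step(params, initial_state(params, np.zeros(2)),
                         np.array([0.0, np.nan, 0.0]))


class TestNLL:
    def test_zero_error_unit_variance(self):
        loss = stepwise_nll(np.zeros(4), np.ones(4), np.zeros(4))
        assert np.allclose(loss, np.log(2 * np.pi) / 2)

    def test_minimizer_over_v_is_squared_error(self):
        e = 0.37
        vgrid = np.linspace(0.01, 1.0, 2000)
        losses = [stepwise_nll(np.array([0.0]), np.array([v]),
                               np.array([e]))[0] for v in vgrid]
        assert vgrid[int(np.argmin(losses))] == pytest.approx(e**2, rel=0.02)

    def test_direct_evaluation(self):
        loss = stepwise_nll(np.array([0.1]), np.array([0.01]), np.array([0.0]))
        assert loss[0] == pytest.approx(0.5 * np.log(2 * np.pi * 0.01) + 0.5)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            stepwise_nll(np.zeros(1), np.zeros(1), np.zeros(1))

    def test_sequence_nll_is_plain_sum(self):
        params = init_parameters(_tiny_config(), 5, n_sequences=1)
        seq = np.random.default_rng(2).uniform(-0.5, 0.5, (6, 3))
        trace = run_open_loop(params, params.u0_pb[0], seq)
        single = sequence_nll(trace)
        assert single == pytest.approx(np.sum(trace.loss))
        assert sequence_nll([trace, trace]) == pytest.approx(2 * single)


class TestRuns:
    def test_open_loop_has_t_minus_one_steps(self):
        params = init_parameters(_tiny_config(), 1, n_sequences=1)
        seq = np.random.default_rng(0).uniform(-0.5, 0.5, (9, 3))
        trace = run_open_loop(params, params.u0_pb[0], seq)
        assert trace.n_steps == 8

    def test_open_loop_rejects_length_one(self):
        params = init_parameters(_tiny_config(), 1, n_sequences=1)
        with pytest.raises(ValueError):
            run_open_loop(params, params.u0_pb[0], np.zeros((1, 3)))

    def test_perfect_predictor_loss_is_entropy_floor(self):
        """y == target and v == 1 gives (T-1) * n_mean * ln(2 pi) / 2."""
        config = _tiny_config()
        params = _zero_params(config)
        T = 7
        seq = np.zeros((T, 3))  # constant zero: the zero network is perfect
        trace = run_open_loop(params, np.zeros(2), seq)
        expected = (T - 1) * 3 * np.log(2 * np.pi) / 2
        assert sequence_nll(trace) == pytest.approx(expected)

    def test_runs_are_deterministic(self):
        params = init_parameters(_tiny_config(), 1, n_sequences=1)
        seq = np.random.default_rng(1).uniform(-0.5, 0.5, (8, 3))
        t1 = run_open_loop(params, params.u0_pb[0], seq)
        t2 = run_open_loop(params, params.u0_pb[0], seq)
        assert np.array_equal(t1.y, t2.y) and np.array_equal(t1.v, t2.v)

    def test_closed_loop_fixed_point_stub(self):
        """An identity-like linear readout holds a fixed point at zero."""
        config = ModelConfig(n_input=1, n_mean=1, n_variance=1, n_context=1,
                             n_pb=1, tau=1.0, bias_variance_k=0.0)
        params = _zero_params(config)
        trace = run_closed_loop(params, np.zeros(1), np.zeros(1), 10)
        assert np.allclose(trace.y, 0.0)

    def test_closed_loop_single_step(self):
        params = init_parameters(_tiny_config(), 1, n_sequences=1)
        trace = run_closed_loop(params, params.u0_pb[0], np.zeros(3), 1)
        assert trace.y.shape == (1, 3)


class TestBPTT:
    def test_gradients_match_central_finite_differences(self, tiny_setup):
        """The analytic BPTT gradient of the summed NLL agrees elementwise
        with a central-difference oracle to < 1e-4 relative error."""
        _, params, seqs = tiny_setup
        params = params.copy()
        grads = bptt_gradients(params, seqs)
        h = 1e-5
        for name in NetworkParameters.TRAINABLE:
            arr = getattr(params, name)
            ana = getattr(grads, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = dataset_nll(params, seqs)
                arr[idx] = orig - h
                lm = dataset_nll(params, seqs)
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(ana[idx]), 1e-6)
                assert abs(fd - ana[idx]) / denom < 1e-4, (name, idx)

    def test_pb_gradients_are_per_sequence_separable(self, tiny_setup):
        _, params, seqs = tiny_setup
        g_both = bptt_gradients(params, seqs)
        g_first = bptt_gradients(params, seqs[:1])
        assert np.allclose(g_both.u0_pb[0], g_first.u0_pb[0])

    def test_stationary_at_constructed_optimum(self):
        """Zero network on a constant-zero target: y = target exactly, so
        the mean pathway's gradient vanishes."""
        config = _tiny_config()
        params = _zero_params(config, n_sequences=1)
        grads = bptt_gradients(params, [np.zeros((6, 3))])
        assert np.allclose(grads.W_context_to_mean, 0.0)
        assert np.allclose(grads.b_mean, 0.0)

    def test_gradients_exclude_context_bias(self, tiny_setup):
        _, params, seqs = tiny_setup
        grads = bptt_gradients(params, seqs)
        assert not hasattr(grads, "b_context")


class TestMomentumUpdate:
    def test_plain_gradient_descent_when_eta_zero(self, tiny_setup):
        _, params, seqs = tiny_setup
        params = params.copy()
        grads = bptt_gradients(params, seqs)
        before = params.b_mean.copy()
        vel = Gradients.zeros_like(params)
        apply_momentum_update(params, grads, vel, alpha=1e-3, eta=0.0)
        assert np.allclose(params.b_mean, before - 1e-3 * grads.b_mean)

    def test_zero_gradient_coasts_on_velocity(self, tiny_setup):
        _, params, _ = tiny_setup
        params = params.copy()
        zero = Gradients.zeros_like(params)
        vel = Gradients.zeros_like(params)
        vel.b_mean[...] = 0.5
        before = params.b_mean.copy()
        apply_momentum_update(params, zero, vel, alpha=1e-3, eta=0.9)
        assert np.allclose(params.b_mean, before + 0.9 * 0.5)

    def test_two_epochs_of_constant_gradient_accumulate(self, tiny_setup):
        """Unrolling the momentum recursion twice: -alpha*g*(1 + 1.9)."""
        _, params, _ = tiny_setup
        params = params.copy()
        g = Gradients.zeros_like(params)
        g.b_mean[...] = 2.0
        vel = Gradients.zeros_like(params)
        before = params.b_mean.copy()
        apply_momentum_update(params, g, vel, alpha=1e-3, eta=0.9)
        apply_momentum_update(params, g, vel, alpha=1e-3, eta=0.9)
        assert np.allclose(params.b_mean, before - 1e-3 * 2.0 * (1 + 1.9))

    def test_context_bias_is_never_touched(self, tiny_setup):
        _, params, seqs = tiny_setup
        params = params.copy()
        frozen = params.b_context.copy()
        vel = Gradients.zeros_like(params)
        for _ in range(5):
            grads = bptt_gradients(params, seqs)
            apply_momentum_update(params, grads, vel, alpha=1e-4, eta=0.9)
        assert np.array_equal(params.b_context, frozen)

    def test_monotone_loss_with_small_plain_steps(self, tiny_setup):
        _, params, seqs = tiny_setup
        params = params.copy()
        vel = Gradients.zeros_like(params)
        losses = [dataset_nll(params, seqs)]
        for _ in range(100):
            grads = bptt_gradients(params, seqs)
            apply_momentum_update(params, grads, vel, alpha=1e-6, eta=0.0)
            losses.append(dataset_nll(params, seqs))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestVarianceFloorToy:
    def test_variance_only_network_recovers_noise_floor(self):
        """A 1-context-neuron net on i.i.d. N(0, sigma^2) targets drives its
        predicted variance toward sigma^2 (v* = e^2 pointwise)."""
        sigma2 = 0.05
        rng = np.random.default_rng(8)
        config = ModelConfig(n_input=1, n_mean=1, n_variance=1, n_context=1,
                             n_pb=1, tau=1.0, bias_variance_k=0.0)
        params = _zero_params(config, n_sequences=1)
        seq = rng.normal(0.0, np.sqrt(sigma2), (80, 1))
        vel = Gradients.zeros_like(params)
        for _ in range(400):
            grads = bptt_gradients(params, [seq])
            # train the variance pathway only; mean stays at its optimum 0
            grads.W_context_to_mean[...] = 0.0
            grads.b_mean[...] = 0.0
            apply_momentum_update(params, grads, vel, alpha=2e-4, eta=0.9)
        trace = run_open_loop(params, params.u0_pb[0], seq)
        vhat = float(np.mean(trace.v))
        target = float(np.mean(seq[1:] ** 2))
        assert abs(vhat - target) / target < 0.2


class TestCheckpoint:
    def test_bit_exact_round_trip(self, tmp_path, tiny_setup):
        config, params, _ = tiny_setup
        save_checkpoint(tmp_path / "ckpt", params, config, extra={"note": 1})
        back, config2, extra = load_checkpoint(tmp_path / "ckpt")
        for f in dataclasses.fields(params):
            assert np.array_equal(getattr(params, f.name),
                                  getattr(back, f.name))
        assert config2 == config
        assert extra == {"note": 1}
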