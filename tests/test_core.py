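"""Single-step dynamics: traces, sigmoids, homeostasis, spiking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replaynet.core import (
    ModelKind,
    NeuronParams,
    NetworkWeights,
    decay_and_jump_trace,
    dynamic_sigmoid,
    init_state,
    init_weights,
    membrane_potential,
    sample_spikes,
    static_sigmoid,
    step_network,
    update_h,
)
from replaynet.engine import run_phase


class TestNeuronParams:
    def test_defaults_match_model_constants(self, params):
        assert params.dt == 1.0
        assert params.tau == 15.0
        assert params.tau_h == 10_000.0
        assert params.phi0 == 50.0
        assert params.g == 3.0
        assert params.beta0 == 5.0
        assert params.theta0 == 1.0
        assert params.eta == 1e-4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": -1.0},
            {"tau": 0.0},
            {"tau_h": 10.0},  # must exceed tau
            {"phi0": -5.0},
            {"eta": 0.0},
            {"h_floor": 0.0},
            {"phi0": 2000.0},  # spike probability > 1
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NeuronParams(**kwargs)


class TestTrace:
    @pytest.mark.parametrize(
        "trace,spiked,dt,tau,expected",
        [
            (1.0, False, 15.0, 15.0, np.exp(-1.0)),
            (0.0, True, 1.0, 15.0, 1.0),
            (0.0, True, 7.3, 4.2, 1.0),
            (0.5, True, 1.0, 15.0, 0.5 * np.exp(-1.0 / 15.0) + 1.0),
        ],
    )
    def test_closed_form(self, trace, spiked, dt, tau, expected):
        assert decay_and_jump_trace(trace, spiked, dt, tau) == pytest.approx(expected)

    def test_negative_time_constants_rejected(self):
        with pytest.raises(ValueError):
            decay_and_jump_trace(1.0, False, -1.0, 15.0)
        with pytest.raises(ValueError):
            decay_and_jump_trace(1.0, False, 1.0, 0.0)

    def test_matches_brute_force_kernel_convolution(self, params, rng):
        """Trace linearity: iterated update equals the sum of per-spike
        exponential kernels on a 1-s raster (tolerance 1e-10)."""
        steps = 1000
        spikes = rng.random(steps) < 0.05
        trace = 0.0
        history = np.empty(steps)
        for t in range(steps):
            trace = decay_and_jump_trace(trace, spikes[t], params.dt, params.tau)
            history[t] = trace
        times = np.nonzero(spikes)[0]
        for t in range(steps):
            past = times[times <= t]
            oracle = np.exp(-(t - past) * params.dt / params.tau).sum()
            assert history[t] == pytest.approx(oracle, abs=1e-10)


class TestSigmoids:
    def test_static_midpoint_is_half_max(self, params):
        assert static_sigmoid(params.g * params.theta0, params) == pytest.approx(
            params.phi0 / 2
        )

    def test_static_limits(self, params):
        assert static_sigmoid(-1e3, params) == pytest.approx(0.0, abs=1e-12)
        assert static_sigmoid(1e3, params) == pytest.approx(params.phi0)

    def test_static_at_zero_potential(self, params):
        # phi(0) = 50/(1+e^45) with the default constants
        expected = params.phi0 / (1.0 + np.exp(params.g**2 * params.beta0 * params.theta0))
        assert static_sigmoid(0.0, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.43e-18, rel=0.01)

    def test_dynamic_midpoint_at_tracked_maximum(self, params):
        # firing reaches phi0/2 exactly when u equals theta0 * h
        for h in (0.2, 1.0, 3.7):
            assert dynamic_sigmoid(params.theta0 * h, h, params) == pytest.approx(
                params.phi0 / 2
            )

    def test_dynamic_limits_and_monotonicity(self, params):
        assert dynamic_sigmoid(-1e4, 1.0, params) == pytest.approx(0.0, abs=1e-12)
        assert dynamic_sigmoid(1e4, 1.0, params) == pytest.approx(params.phi0)
        u = np.linspace(-3, 6, 200)
        f = dynamic_sigmoid(u, 1.3, params)
        assert (np.diff(f) >= 0).all()
        mid = (u > 0.5) & (u < 2.0)  # strictly increasing off saturation
        assert (np.diff(f[mid]) > 0).all()

    def test_dynamic_scale_invariance(self, params):
        """The homeostatic rescaling acts only through u/h."""
        u, h = 1.7, 2.2
        assert dynamic_sigmoid(u, h, params) == pytest.approx(
            dynamic_sigmoid(3 * u, 3 * h, params)
        )

    def test_h_below_floor_is_clamped_not_divided(self, params):
        val = dynamic_sigmoid(0.5, 0.0, params)
        assert np.isfinite(val)
        assert val == pytest.approx(dynamic_sigmoid(0.5, params.h_floor, params))

    @given(
        u=st.floats(-50, 50),
        h=st.floats(0.01, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_rates_bounded(self, u, h):
        p = NeuronParams()
        f = dynamic_sigmoid(u, h, p)
        assert 0.0 <= f <= p.phi0


class TestUpdateH:
    def test_decay_branch_closed_form(self, params):
        assert update_h(2.0, 1.0, params) == pytest.approx(2.0 * np.exp(-1e-4))

    def test_jump_branch(self, params):
        assert update_h(1.0, 3.0, params) == pytest.approx(3.0)

    def test_boundary_h_equals_u(self, params):
        assert update_h(1.5, 1.5, params) == pytest.approx(1.5)

    def test_floor_clamp(self, params):
        assert update_h(params.h_floor, -5.0, params) == pytest.approx(params.h_floor)

    def test_non_increasing_envelope_between_jumps(self, params):
        """With u held below h, h decreases monotonically toward the floor."""
        h = 2.0
        values = []
        for _ in range(500):
            h = update_h(h, 0.1, params)
            values.append(float(h))
        assert all(b < a for a, b in zip(values, values[1:]))
        # integrate the decay analytically over n steps
        n = 500
        assert values[-1] == pytest.approx(2.0 * np.exp(-n * params.dt / params.tau_h))


class TestSampleSpikes:
    def test_zero_rate_is_silent(self, params, rng):
        assert sample_spikes(np.zeros(50), params.dt, rng).sum() == 0

    def test_empirical_rate_matches(self, params):
        rng = np.random.default_rng(7)
        steps, rate = 100_000, 50.0
        total = sum(
            int(sample_spikes(np.array([rate]), params.dt, rng)[0])
            for _ in range(steps)
        )
        measured = total / (steps * params.dt / 1000.0)
        se = 1000.0 / steps * np.sqrt(steps * (rate / 1000) * (1 - rate / 1000))
        assert abs(measured - rate) < 3 * se

    def test_deterministic_given_seed(self, params):
        f = np.full(100, 30.0)
        a = sample_spikes(f, params.dt, np.random.default_rng(3))
        b = sample_spikes(f, params.dt, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_rejects_invalid_probability(self, params, rng):
        with pytest.raises(ValueError):
            sample_spikes(np.array([2000.0]), params.dt, rng)
        with pytest.raises(ValueError):
            sample_spikes(np.array([-1.0]), params.dt, rng)


class TestMembranePotential:
    def test_zero_weights_zero_potential(self, rng):
        w = init_weights(ModelKind.NDL, 4, 6, rng)
        for m in (w.W, w.M, w.G):
            m[...] = 0.0
        u, comps = membrane_potential(w, np.ones(6), np.ones(4))
        assert np.allclose(u, 0.0)
        assert np.allclose(comps["v_W"], 0.0)

    def test_ndl_hand_example(self):
        w = NetworkWeights(
            kind=ModelKind.NDL,
            W=np.array([[2.0]]),
            M=np.array([[0.0]]),
            G=np.array([[1.0]]),
        )
        u, comps = membrane_potential(w, np.array([0.5]), np.array([1.0]))
        assert u[0] == pytest.approx(2.0 * 0.5 - 1.0)
        assert comps["v_W"][0] == pytest.approx(1.0)
        assert comps["v_G"][0] == pytest.approx(1.0)

    def test_signed_exc_inh_cancellation(self, rng):
        w = init_weights(ModelKind.SIGNED, 5, 8, rng)
        w.M_exc = np.abs(rng.normal(size=(5, 5)))
        w.M_inh = w.M_exc.copy()
        y = rng.random(5)
        _, comps = membrane_potential(w, np.zeros(8), y)
        assert np.allclose(comps["v_M_exc"] - comps["v_M_inh"], 0.0)

    def test_shape_mismatch_raises(self, rng):
        w = init_weights(ModelKind.NDL, 4, 6, rng)
        with pytest.raises(ValueError):
            membrane_potential(w, np.ones(5), np.ones(4))

    def test_dl_components(self, rng):
        w = init_weights(ModelKind.DL, 6, 4, rng, n_exc=4)
        y = rng.random(6)
        u, comps = membrane_potential(w, np.zeros(4), y)
        v_M2 = w.M_XE @ y[:4] - w.G_path2 @ y[4:]
        v_M1 = w.G_path1 @ y[4:]
        assert np.allclose(comps["v_M2"], v_M2)
        assert np.allclose(u, v_M2 - v_M1)


class TestStepNetwork:
    def test_zero_weights_rate_is_baseline(self, params, rng):
        w = init_weights(ModelKind.NDL, 10, 5, rng)
        for m in (w.W, w.M, w.G):
            m[...] = 0.0
        st_ = init_state(10, 5, params)
        step_network(st_, w, np.ones(5, dtype=np.uint8), params, rng)
        assert np.allclose(st_.f, dynamic_sigmoid(0.0, st_.h, params))

    def test_spontaneous_mode_ignores_input(self, params):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        w1 = init_weights(ModelKind.NDL, 10, 5, np.random.default_rng(1))
        w2 = w1.copy()
        s1 = init_state(10, 5, params)
        s2 = init_state(10, 5, params)
        step_network(s1, w1, np.ones(5, dtype=np.uint8), params, rng1, mode="spontaneous")
        step_network(s2, w2, None, params, rng2, mode="spontaneous")
        assert np.array_equal(s1.spikes, s2.spikes)
        assert np.allclose(s1.u, s2.u)

    def test_unknown_mode_rejected(self, params, rng):
        w = init_weights(ModelKind.NDL, 4, 3, rng)
        with pytest.raises(ValueError):
            step_network(init_state(4, 3, params), w, None, params, rng, mode="noisy")

    def test_nan_potential_aborts(self, params, rng):
        w = init_weights(ModelKind.NDL, 4, 3, rng)
        w.W[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            step_network(init_state(4, 3, params), w,
                         np.ones(3, dtype=np.uint8), params, rng)

    def test_h_relaxes_toward_floor_without_drive(self, params, rng):
        """Repeated stepping with u ~ 0 < h decays h with time constant
        tau_h, matching the analytic exponential."""
        w = init_weights(ModelKind.NDL, 6, 3, rng)
        for m in (w.W, w.M, w.G):
            m[...] = 0.0
        st_ = init_state(6, 3, params)
        n = 5000
        for _ in range(n):
            step_network(st_, w, None, params, rng, mode="spontaneous")
        assert np.allclose(st_.h, params.theta0 * np.exp(-n * params.dt / params.tau_h),
                           rtol=1e-6)


class TestEngineAgreement:
    @pytest.mark.parametrize("kind", [ModelKind.NDL, ModelKind.SIGNED, ModelKind.DL])
    def test_run_phase_matches_step_network(self, params, kind):
        """The fused integrator reproduces the reference single-step path
        to floating-point round-off, spike for spike."""
        N, K, steps = 12, 8, 400
        w_a = init_weights(kind, N, K, np.random.default_rng(2), n_exc=6)
        w_b = w_a.copy()
        s_a = init_state(N, K, params)
        s_b = init_state(N, K, params)
        rates = np.full(K, 40.0)
        rng_a = np.random.default_rng(9)
        rec = run_phase(w_a, s_a, params, rng_a, steps,
                        input_segments=[(0.0, float(steps), rates)],
                        plastic=frozenset({"W"}))
        # mirror the engine's draw order: one input block, then per-step spikes
        rng_b = np.random.default_rng(9)
        inp = rng_b.random((steps, K)) < rates * params.dt / 1000.0
        counts = np.zeros(N)
        for t in range(steps):
            step_network(s_b, w_b, inp[t].astype(np.uint8), params, rng_b,
                         plastic={"W"})
            counts += s_b.spikes
        assert np.array_equal(rec.counts, counts)
        assert np.allclose(s_a.u, s_b.u, rtol=1e-10, atol=1e-12)
        assert np.allclose(w_a.W, w_b.W, rtol=1e-10, atol=1e-14)

    def test_determinism_same_seed_identical_trajectories(self, params):
        N, K, steps = 10, 6, 300
        results = []
        for _ in range(2):
            w = init_weights(ModelKind.NDL, N, K, np.random.default_rng(4))
            s = init_state(N, K, params)
            rec = run_phase(w, s, params, np.random.default_rng(11), steps,
                            input_segments=[(0.0, float(steps), np.full(K, 20.0))],
                            plastic=frozenset({"W", "M", "G"}))
            results.append((rec.counts.copy(), w.W.copy(), w.M.copy(), w.G.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        for a, b in zip(results[0][1:], results[1][1:]):
            assert np.array_equal(a, b)


class TestInitialization:
    def test_gaussian_widths_and_uniform_g(self, rng):
        N, K = 400, 900
        w = init_weights(ModelKind.NDL, N, K, rng)
        assert w.W.std() == pytest.approx(np.sqrt(0.1 / np.sqrt(K)), rel=0.05)
        assert w.M.std() == pytest.approx(np.sqrt(0.1 / np.sqrt(N)), rel=0.05)
        assert abs(w.W.mean()) < 5 * w.W.std() / np.sqrt(N * K)
        assert np.all(w.G == 1.0 / np.sqrt(N))

    def test_sd_reading_is_narrower(self, rng):
        w = init_weights(ModelKind.NDL, 200, 400, rng, init_width="sd")
        assert w.W.std() == pytest.approx(0.1 / np.sqrt(400), rel=0.1)

    def test_signed_masks_partition_pairs(self, rng):
        w = init_weights(ModelKind.SIGNED, 60, 10, rng)
        total = w.mask_exc.astype(int) + w.mask_inh.astype(int) + w.mask_G.astype(int)
        assert np.all(total == 1)
        # ~50/25/25 split
        assert w.mask_exc.mean() == pytest.approx(0.5, abs=0.05)
        assert w.mask_inh.mean() == pytest.approx(0.25, abs=0.05)
        # matrices vanish off their masks and are non-negative
        assert np.all(w.M_exc[~w.mask_exc] == 0)
        assert np.all(w.M_inh >= 0)

    def test_consistency_check_catches_negative_G(self, rng):
        w = init_weights(ModelKind.NDL, 5, 5, rng)
        w.G[0, 0] = -0.1
        with pytest.raises(ValueError):
            w.check_consistency()
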