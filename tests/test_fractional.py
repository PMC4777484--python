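"""L1 discretization, memory trace, and the hybrid integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frachh import (ConfigError, DivergenceError, FractionalConfig,
                    StepCurrentProtocol, fractional_gate_step, l1_weights,
                    memory_trace, rate, simulate_classic, simulate_hybrid,
                    steady_state)
from conftest import naive_l1_gate_sequence


class TestL1Weights:
    def test_eta_one_weights_vanish(self):
        assert np.all(l1_weights(100, 1.0) == 0.0)

    def test_hand_computed_n3(self):
        w = l1_weights(3, 0.5)
        assert w[0] == pytest.approx(math.sqrt(3) - math.sqrt(2), rel=1e-12)
        assert w[1] == pytest.approx(math.sqrt(2) - 1.0, rel=1e-12)

    @given(eta=st.floats(0.05, 0.999), N=st.integers(2, 400))
    @settings(max_examples=100, deadline=None)
    def test_positive_and_increasing(self, eta, N):
        """Recent increments always weigh more (the power-law kernel)."""
        w = l1_weights(N, eta)
        assert np.all(w > 0.0)
        assert np.all(np.diff(w) >= -1e-15)

    def test_monotone_at_large_n(self):
        w = l1_weights(1000, 0.2)
        assert np.all(np.diff(w) > 0.0)

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            l1_weights(1, 0.5)
        with pytest.raises(ConfigError):
            l1_weights(10, 0.0)
        with pytest.raises(ConfigError):
            l1_weights(10, 1.5)


class TestMemoryTrace:
    def test_constant_history_gives_zero(self):
        assert memory_trace(np.full(50, 0.3), 0.6) == 0.0

    def test_two_sample_history_is_empty_sum(self):
        assert memory_trace([0.0, 1.0], 0.5) == 0.0

    def test_eta_one_always_zero(self):
        rng = np.random.default_rng(42)
        assert memory_trace(rng.random(30), 1.0) == 0.0

    def test_matches_naive_double_loop(self):
        """Vectorized trace equals the direct summation at each length."""
        rng = np.random.default_rng(7)
        x = rng.random(50)
        eta = 0.6
        for L in range(3, 51):
            N = L - 1  # trace at the time of sample L-1
            direct = -sum(
                (x[k + 1] - x[k]) *
                ((N - k) ** (1 - eta) - (N - 1 - k) ** (1 - eta))
                for k in range(0, N - 1))
            assert memory_trace(x[:L], eta) == pytest.approx(
                direct, rel=1e-12, abs=1e-13)


class TestFractionalGateStep:
    def test_eta_one_is_forward_euler(self):
        V, x = -30.0, 0.4
        got = fractional_gate_step([0.2, 0.3, x], V, 1.0, 0.01, "n")
        a, b = rate("n", "alpha", V), rate("n", "beta", V)
        euler = x + 0.01 * (a * (1 - x) - b * x)
        assert got == pytest.approx(euler, rel=1e-14)

    def test_steady_state_is_fixed_point(self):
        V = 10.0
        xinf = steady_state(V).n
        got = fractional_gate_step(np.full(20, xinf), V, 0.5, 0.01, "n")
        assert got == pytest.approx(xinf, abs=1e-14)

    def test_matches_naive_sequence_under_clamp(self):
        """20 explicit steps at V = 30 equal the naive implementation."""
        V, eta, dt = 30.0, 0.5, 0.01
        a, b = rate("n", "alpha", V), rate("n", "beta", V)
        x0 = steady_state(0.0).n
        xs, _ = naive_l1_gate_sequence(x0, a, b, eta, dt, 20)
        hist = [x0]
        for i in range(20):
            hist.append(fractional_gate_step(hist, V, eta, dt, "n"))
        np.testing.assert_allclose(hist, xs, rtol=1e-12)

    def test_divergence_raises(self):
        with pytest.raises(DivergenceError):
            fractional_gate_step([0.0, 100.0], -65.0, 0.5, 0.01, "n",
                                 divergence_bound=10.0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"eta": 0.0}, {"eta": 1.5}, {"fractional_gate": "x"},
        {"dt": 0.0}, {"truncation": "half"}, {"truncation": 0},
        {"divergence_bound": -1.0},
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            FractionalConfig(**kwargs)


class TestHybridIntegrator:
    def test_eta_one_reduces_to_classic(self):
        """Memory trace identically zero; voltage matches RK4 classic.

        Over a long tonic train the O(dt) forward-Euler gate step
        accumulates a tiny spike-phase drift, so the pointwise voltage
        comparison uses the first 100 ms and the full 500 ms is checked
        through the spike times.
        """
        from frachh.spikes import detect_spikes
        proto = StepCurrentProtocol(amplitude=18.0, duration=500.0)
        fc = FractionalConfig(fractional_gate="n", eta=1.0, dt=0.001)
        hyb = simulate_hybrid(fconfig=fc, protocol=proto)
        cls = simulate_classic(protocol=proto, dt=0.001)
        assert np.all(hyb.memtrace == 0.0)
        n30 = int(round(30.0 / 0.001))
        assert np.max(np.abs(hyb.V[:n30] - cls.V[:n30])) < 0.5
        th = detect_spikes(hyb).spike_times
        tc = detect_spikes(cls).spike_times
        assert len(th) == len(tc)
        assert np.max(np.abs(th - tc)) < 0.05

    def test_gate_none_is_classic(self):
        proto = StepCurrentProtocol(amplitude=5.0, duration=20.0)
        fc = FractionalConfig(fractional_gate="none", dt=0.01)
        hyb = simulate_hybrid(fconfig=fc, protocol=proto)
        cls = simulate_classic(protocol=proto, dt=0.01)
        np.testing.assert_array_equal(hyb.V, cls.V)

    def test_memtrace_channel_recorded(self):
        fc = FractionalConfig(fractional_gate="n", eta=0.7, dt=0.01)
        tr = simulate_hybrid(fconfig=fc, protocol=StepCurrentProtocol(
            amplitude=10.0, duration=50.0))
        assert tr.memtrace is not None and np.any(tr.memtrace != 0.0)
        assert "memtrace" in tr.to_frame().columns

    def test_m_gate_instability_raises(self):
        """The documented low-eta m-gate instability surfaces as an
        error carrying the (gate, eta, dt) triple, not as garbage."""
        fc = FractionalConfig(fractional_gate="m", eta=0.2, dt=0.01)
        with pytest.raises(DivergenceError) as exc:
            simulate_hybrid(fconfig=fc, protocol=StepCurrentProtocol(
                amplitude=9.0, duration=500.0))
        err = exc.value
        assert err.gate == "m" and err.eta == 0.2 and err.dt == 0.01
        assert err.time_ms is not None

    def test_windowed_full_length_equals_full_memory(self):
        proto = StepCurrentProtocol(amplitude=12.0, duration=20.0)
        full = simulate_hybrid(
            fconfig=FractionalConfig("n", 0.6, 0.01, "full"),
            protocol=proto)
        win = simulate_hybrid(
            fconfig=FractionalConfig("n", 0.6, 0.01, 4000),
            protocol=proto)
        np.testing.assert_array_equal(full.V, win.V)
        np.testing.assert_array_equal(full.memtrace, win.memtrace)

    def test_windowed_truncation_reports_error_bound(self):
        proto = StepCurrentProtocol(amplitude=12.0, duration=20.0)
        win = simulate_hybrid(
            fconfig=FractionalConfig("n", 0.6, 0.01, 200),
            protocol=proto)
        assert win.truncation_error_bound is not None
        assert win.truncation_error_bound > 0.0

    def test_hybrid_matches_naive_oracle(self):
        """Full hybrid trace vs an independent step-by-step rebuild using
        fractional_gate_step (which itself matches the naive loops)."""
        fc = FractionalConfig(fractional_gate="h", eta=0.6, dt=0.02)
        proto = StepCurrentProtocol(amplitude=8.0, duration=6.0)
        tr = simulate_hybrid(fconfig=fc, protocol=proto)
        hist = [tr.h[0]]
        for i in range(1, len(tr)):
            nxt = fractional_gate_step(hist, tr.V[i - 1], 0.6, 0.02, "h")
            hist.append(nxt)
            assert nxt == pytest.approx(tr.h[i], rel=1e-10, abs=1e-12)
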