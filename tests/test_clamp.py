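"""Voltage-clamp characterization: x_inf^eta, exponential fits, m.s.e."""

import numpy as np
import pytest

from frachh import (ConfigError, InputError, VoltageClampProtocol,
                    estimate_xinf_eta, fit_exponentials,
                    numeric_vs_analytic_mse, run_gate_clamp, steady_state,
                    time_constant, xinf_sweep)
from frachh.clamp import GateClampTrace


def clamp(gate, V, eta, dt=0.01, dur=None):
    from frachh.clamp import XINF_READ_TIME
    proto = VoltageClampProtocol(target_V=V,
                                 target_duration=dur or
                                 XINF_READ_TIME[gate])
    return run_gate_clamp(gate, proto, eta=eta, dt=dt)


class TestRunGateClamp:
    def test_classic_limit_single_exponential_rise(self):
        """At eta = 1 the n gate relaxes exponentially to n_inf(30)."""
        tr = clamp("n", 30.0, 1.0)
        ts, xs = tr.target_phase()
        tau = time_constant(30.0, "n")
        ninf = steady_state(30.0).n
        x0 = steady_state(0.0).n
        expect = ninf + (x0 - ninf) * np.exp(-ts / tau)
        assert np.max(np.abs(xs - expect)) < 1e-3

    def test_fractional_curves_cross_classic(self):
        """eta = 0.5 rises faster early and approaches slower late, so
        the curves cross the eta = 1 response."""
        t5 = clamp("n", 30.0, 0.5)
        t1 = clamp("n", 30.0, 1.0)
        _, x5 = t5.target_phase()
        _, x1 = t1.target_phase()
        d = x5 - x1
        i_early = int(0.2 / 0.01)
        assert d[i_early] > 0.0          # faster early rise
        assert d[-1] < 0.0               # slower late approach
        assert np.any(np.sign(d[1:]) != np.sign(d[1]))

    def test_hold_phase_is_constant(self):
        tr = clamp("h", -70.0, 0.5)
        x0 = steady_state(0.0).h
        assert np.all(tr.x[:tr.onset_index] == x0)

    def test_bad_arguments(self):
        with pytest.raises(InputError):
            run_gate_clamp("z", eta=0.5)
        with pytest.raises(ConfigError):
            run_gate_clamp("n", eta=0.0)
        with pytest.raises(ConfigError):
            VoltageClampProtocol(hold_duration=0.0)


class TestXinfEta:
    def test_classic_sweep_reproduces_sigmoid(self):
        """At eta = 1 the long-term response equals alpha/(alpha+beta)."""
        Vs = np.arange(-100.0, 121.0, 20.0)
        _, xs, conv = xinf_sweep("n", 1.0, Vs, dt=0.01)
        expect = [steady_state(V).n for V in Vs]
        np.testing.assert_allclose(xs, expect, atol=1e-3)
        assert conv.all()

    def test_inflection_slope_shallower_for_n(self):
        """Power-law dynamics flattens the n-gate activation curve."""
        Vs = np.arange(-70.0, -39.0, 10.0)   # around the inflection
        _, x1, _ = xinf_sweep("n", 1.0, Vs, dt=0.01)
        _, x4, _ = xinf_sweep("n", 0.4, Vs, dt=0.01)
        slope1 = np.max(np.diff(x1))
        slope4 = np.max(np.diff(x4))
        assert slope4 < slope1

    def test_m_gate_slope_barely_changes(self):
        Vs = np.arange(-60.0, -29.0, 10.0)
        _, x1, _ = xinf_sweep("m", 1.0, Vs, dt=0.01)
        _, x4, _ = xinf_sweep("m", 0.4, Vs, dt=0.01)
        slope1 = np.max(np.diff(x1))
        slope4 = np.max(np.diff(x4))
        assert abs(slope4 - slope1) < 0.1 * slope1

    def test_short_trace_rejected(self):
        tr = clamp("n", 30.0, 1.0, dur=10.0)
        with pytest.raises(InputError):
            estimate_xinf_eta(tr)


class TestFitExponentials:
    def test_classic_fit_degenerates_to_single_tau(self):
        """On eta = 1 traces both time constants equal the classic tau."""
        for gate, V in (("n", 30.0), ("h", -70.0)):
            fit = fit_exponentials(clamp(gate, V, 1.0), 2)
            tau = time_constant(V, gate)
            assert fit.tau_fast == pytest.approx(tau, rel=0.02)
            assert fit.tau_slow == pytest.approx(tau, rel=0.02)
            assert fit.tau_fast <= fit.tau_slow

    def test_fast_slow_split_grows_as_eta_drops(self):
        """tau_fast accelerates and tau_slow slows with decreasing eta."""
        tf, tsl = [], []
        for eta in (1.0, 0.8, 0.6, 0.4):
            fit = fit_exponentials(clamp("n", 30.0, eta), 2)
            tf.append(fit.tau_fast)
            tsl.append(fit.tau_slow)
        assert np.all(np.diff(tf) < 0.0)
        assert np.all(np.diff(tsl) > 0.0)

    def test_recovers_known_two_exponential_data(self):
        """Parameter recovery on synthetic dual-exponential data."""
        ts = np.arange(0.0, 100.0, 0.01)
        xs = 0.9 - 0.3 * np.exp(-ts / 2.0) - 0.4 * np.exp(-ts / 20.0)
        proto = VoltageClampProtocol(target_V=30.0, target_duration=100.0)
        tr = GateClampTrace(
            t=np.concatenate([np.arange(-25.0, 0.0, 0.01), ts]) + 25.0,
            x=np.concatenate([np.full(2500, xs[0]), xs]),
            memtrace=np.zeros(2500 + len(ts)), gate_id="n", eta=0.5,
            dt=0.01, protocol=proto, onset_index=2500)
        fit = fit_exponentials(tr, 2)
        assert fit.tau_fast == pytest.approx(2.0, rel=0.05)
        assert fit.tau_slow == pytest.approx(20.0, rel=0.05)
        assert fit.x_inf_fit == pytest.approx(0.9, rel=0.05)

    def test_component_count_validated(self):
        with pytest.raises(ConfigError):
            fit_exponentials(clamp("n", 30.0, 1.0), 3)


class TestMse:
    def test_classic_limit_tiny(self):
        """eta = 1 m.s.e. is pure Euler-vs-exponential discretization."""
        res = numeric_vs_analytic_mse("n", etas=[1.0], Vs=[-60.0, 30.0],
                                      dt=0.001, compare_every=10)
        assert res.average < 1e-8

    def test_decreases_with_dt(self):
        vals = []
        for dt in (0.01, 0.001):
            res = numeric_vs_analytic_mse("n", etas=[0.5],
                                          Vs=[-60.0, 30.0], dt=dt,
                                          compare_every=10)
            vals.append(res.average)
        assert vals[1] < vals[0]

    def test_gate_values_bounded_in_sweep(self):
        """Clamp traces stay within [-0.01, 1.01] where the explicit L1
        scheme is stable: the full sweep for the slow n and h gates, and
        the depolarized range for the fast m gate (hyperpolarized m-gate
        clamps at low eta exceed the explicit-scheme stability limit and
        raise DivergenceError instead of returning bounded garbage)."""
        for gate in ("n", "h"):
            for eta in (0.3, 0.6, 1.0):
                for V in (-100.0, 0.0, 120.0):
                    tr = clamp(gate, V, eta)
                    assert tr.x.min() > -0.01 and tr.x.max() < 1.01
        for eta in (0.4, 0.6, 1.0):
            for V in (-40.0, 0.0, 120.0):
                tr = clamp("m", V, eta, dt=0.001)
                assert tr.x.min() > -0.01 and tr.x.max() < 1.01
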