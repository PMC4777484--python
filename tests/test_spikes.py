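"""Spike detection, shape metrics, rheobase, and phase-plane currents."""

import numpy as np
import pytest

from frachh import (FractionalConfig, HHParams, InputError, SimTrace,
                    StepCurrentProtocol, UndefinedWidthError,
                    current_threshold, detect_spikes, half_width,
                    phase_plane, simulate_classic, voltage_threshold)
from frachh.spikes import minimum_spiking_trace


def synthetic_trace(t, V):
    return SimTrace(t=t, V=V, n=np.zeros_like(t), m=np.zeros_like(t),
                    h=np.zeros_like(t), dt=float(t[1] - t[0]),
                    protocol=StepCurrentProtocol(amplitude=0.0, onset=0.0,
                                                 duration=float(t[-1])))


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 0.01)
        f = detect_spikes(synthetic_trace(t, np.full_like(t, -65.0)))
        assert f.n_spikes == 0

    def test_gaussian_bumps_recovered_exactly(self):
        """Synthetic +30 mV bumps at known times are all found, at the
        right peak times."""
        t = np.arange(0.0, 200.0, 0.01)
        centers = np.array([20.0, 57.0, 103.0, 160.0])
        V = np.full_like(t, -65.0)
        for c in centers:
            V += 95.0 * np.exp(-0.5 * ((t - c) / 0.5) ** 2)
        f = detect_spikes(synthetic_trace(t, V))
        np.testing.assert_allclose(f.spike_times, centers, atol=0.02)
        assert np.all(f.peak_V > 25.0)

    def test_subthreshold_oscillations_not_counted(self):
        t = np.arange(0.0, 300.0, 0.01)
        V = -60.0 + 5.0 * np.sin(2 * np.pi * 0.03 * t)  # peaks at -55
        assert detect_spikes(synthetic_trace(t, V)).n_spikes == 0

    def test_classic_rate_84hz(self, classic_i18_trace):
        f = detect_spikes(classic_i18_trace)
        assert f.firing_rate == pytest.approx(84.0, abs=1.0)

    def test_rate_consistent_with_isi(self, classic_i18_trace):
        f = detect_spikes(classic_i18_trace)
        isi_rate = 1000.0 / np.mean(np.diff(f.spike_times))
        assert f.firing_rate == pytest.approx(isi_rate, rel=0.05)


class TestHalfWidth:
    def test_triangular_spike_geometry(self):
        """A symmetric triangular spike of 2-ms base has width 1 ms at
        half height (identical for both baseline conventions)."""
        t = np.arange(0.0, 40.0, 0.001)
        V = np.full_like(t, -65.0)
        tri = 1.0 - np.abs(t - 20.0)  # 2-ms base, apex at t=20
        V += np.maximum(tri, 0.0) * 95.0
        tr = synthetic_trace(t, V)
        assert half_width(tr, 0, baseline="trough") == pytest.approx(
            1.0, abs=1e-3)
        assert half_width(tr, 0, baseline="threshold") == pytest.approx(
            1.0, abs=1e-3)

    def test_decimation_invariance(self, classic_i18_trace):
        """Interpolation makes the width robust to 2x decimation."""
        w1 = half_width(classic_i18_trace, 1)
        w2 = half_width(classic_i18_trace.decimate(2), 1)
        assert w2 == pytest.approx(w1, abs=0.02)

    def test_plateau_raises_undefined_width(self):
        t = np.arange(0.0, 200.0, 0.01)
        V = np.full_like(t, -65.0)
        V[(t > 20.0)] = 10.0      # upstroke then permanent plateau
        with pytest.raises(UndefinedWidthError):
            half_width(synthetic_trace(t, V), 0)

    def test_missing_spike_rejected(self, quiescent_trace):
        with pytest.raises(InputError):
            half_width(quiescent_trace, 0)


class TestVoltageThreshold:
    def test_sanity_envelope_classic(self, classic_i18_trace):
        """All spiking thresholds land in the physiological window."""
        f = detect_spikes(classic_i18_trace)
        for i in range(min(f.n_spikes, 10)):
            v = voltage_threshold(classic_i18_trace, i, f)
            assert -60.0 < v < -40.0

    def test_slow_ramp_raises(self):
        t = np.arange(0.0, 100.0, 0.01)
        V = -65.0 + t * 1.0   # 1 mV/ms, never exceeds 20 mV/ms
        V = np.minimum(V, 5.0)
        with pytest.raises(InputError):
            voltage_threshold(synthetic_trace(t, V), 0)


class TestCurrentThreshold:
    def test_classic_grid_vs_fine_bisection(self):
        """The 0.5-nA grid answer brackets a fine bisection oracle."""
        fc = FractionalConfig(fractional_gate="none", dt=0.01)
        th = current_threshold(fconfig=fc)
        assert th.first_spike_I is not None

        def spikes_at(I):
            from frachh import simulate_hybrid
            tr = simulate_hybrid(
                None, fc, StepCurrentProtocol(amplitude=I, duration=500.0),
                max_spikes=2)
            return detect_spikes(tr).n_spikes

        lo, hi = th.first_spike_I - 0.5, th.first_spike_I
        assert spikes_at(hi) >= 1
        if lo > 0:
            assert spikes_at(lo) == 0
        # bisection refine to 0.01 nA must stay within one grid step
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            if spikes_at(mid) >= 1:
                hi = mid
            else:
                lo = mid
        assert abs(hi - th.first_spike_I) <= th.grid_step

    def test_no_spiking_yields_sentinel(self):
        weak = HHParams(gNa_bar=1.0)     # cannot spike
        th = current_threshold(params=weak,
                               fconfig=FractionalConfig(dt=0.01),
                               I_grid=[1.0, 2.0])
        assert th.first_spike_I is None and th.repetitive_I is None

    def test_descending_grid_rejected(self):
        with pytest.raises(InputError):
            current_threshold(I_grid=[5.0, 1.0])


class TestPhasePlane:
    def test_imbalance_is_exact_sum(self, classic_i18_trace):
        pp = phase_plane(classic_i18_trace)
        np.testing.assert_array_equal(pp.imbalance, pp.I_Na + pp.I_w)

    def test_sign_convention(self, classic_i18_trace):
        """I_Na is depolarizing (positive during the upstroke) and the
        stored currents balance C dV/dt."""
        tr = classic_i18_trace
        pp = phase_plane(tr)
        f = detect_spikes(tr)
        up = f.upstroke_index[1]
        assert pp.I_Na[up] > 0.0
        dVdt = np.gradient(tr.V, tr.dt)
        np.testing.assert_allclose(tr.params.C * dVdt[2:-2],
                                   pp.imbalance[2:-2], atol=5e-2)

    def test_classic_orbit_closes(self, classic_i18_trace):
        """Successive tonic-spiking cycles retrace the same (I_Na, I_w)
        orbit to within 1% of its diameter."""
        tr = classic_i18_trace
        pp = phase_plane(tr)
        f = detect_spikes(tr)
        i3, i4, i5 = f.peak_index[3:6]
        a = np.stack([pp.I_Na[i3:i4], pp.I_w[i3:i4]])
        b = np.stack([pp.I_Na[i4:i5], pp.I_w[i4:i5]])
        L = min(a.shape[1], b.shape[1])
        grid = np.linspace(0.0, 1.0, 400)
        ai = np.stack([np.interp(grid, np.linspace(0, 1, a.shape[1]),
                                 a[k]) for k in range(2)])
        bi = np.stack([np.interp(grid, np.linspace(0, 1, b.shape[1]),
                                 b[k]) for k in range(2)])
        diam = np.max(np.linalg.norm(
            ai[:, :, None] - ai[:, None, :], axis=0))
        dist = np.max(np.linalg.norm(ai - bi, axis=0))
        assert dist < 0.01 * diam

    def test_mmo_attractor_balances_currents(self, mmo_trace):
        """At the MMO sub-threshold attractor the sodium and restoring
        currents balance: the imbalance current hovers near zero while
        I_w itself is strongly repolarizing."""
        from frachh import detect_subthreshold_oscillations
        pp = phase_plane(mmo_trace)
        f = detect_spikes(mmo_trace)
        osc = detect_subthreshold_oscillations(mmo_trace, f)
        assert len(osc) > 5
        idx = np.searchsorted(mmo_trace.t, osc)
        assert abs(np.mean(pp.imbalance[idx])) < 2.0
        assert -50.0 < np.mean(pp.I_w[idx]) < -10.0


class TestMinimumSpikingTrace:
    def test_classic_rheobase_trace(self):
        fc = FractionalConfig(fractional_gate="none", dt=0.01)
        I, tr = minimum_spiking_trace(fconfig=fc)
        assert 1.0 < I < 24.0
        assert detect_spikes(tr).n_spikes >= 2
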