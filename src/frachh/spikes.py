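"""Spike detection and characterization, and phase-plane current analysis.

Spike criterion: an upward crossing of 0 mV followed by a local maximum,
with >= 2 ms separation between successive crossings.  Sub-threshold
oscillations in this model stay well below -20 mV (pseudo-plateau events
are handled by the pattern classifier, not here), so the 0-mV criterion is
unambiguous for every pattern type.

Spike-shape metrics follow the conventions used for the single-action-
potential analyses: the characterized spike is the *second* one at the
minimum input current that elicits repetitive spiking; the half-width
baseline is the pre-spike trough (minimum voltage in the 20 ms preceding
the peak); the voltage threshold is the voltage at which dV/dt first
exceeds 20 mV/ms on the upstroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, UndefinedWidthError
from .fractional import FractionalConfig, simulate_hybrid
from .hh_core import HHParams, SimTrace, StepCurrentProtocol

MIN_SEPARATION_MS = 2.0
DVDT_THRESHOLD = 20.0          # mV/ms, voltage-threshold criterion
HALF_WIDTH_BASELINE_MS = 20.0  # pre-peak window defining the trough baseline


@dataclass
class SpikeFeatures:
    """Per-spike times/peaks and trace-level firing rate.

    ``spike_times`` are the times of the spike peaks (ms), strictly
    increasing.  ``firing_rate`` is the spike count divided by the active
    (stimulus) window, in Hz.
    """

    spike_times: np.ndarray
    peak_V: np.ndarray
    peak_index: np.ndarray
    upstroke_index: np.ndarray   # sample of the 0-mV crossing
    firing_rate: float
    half_width: list = field(default_factory=list)
    voltage_threshold: list = field(default_factory=list)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def detect_spikes(trace: SimTrace, stim_window=None) -> SpikeFeatures:
    """Detect spikes as 0-mV upcrossings followed by a local maximum.

    Successive upcrossings closer than 2 ms are merged into one event, so
    sub-threshold oscillations and plateau ripples are not double-counted.
    The firing rate is count / stimulus-duration (the trace's protocol
    window by default).
    """
    V = trace.V
    t = trace.t
    up = np.flatnonzero((V[:-1] < 0.0) & (V[1:] >= 0.0))
    events = []
    last_t = -np.inf
    for i in up:
        if t[i + 1] - last_t < MIN_SEPARATION_MS:
            continue
        last_t = t[i + 1]
        events.append(i + 1)
    peaks = []
    peak_idx = []
    upstrokes = []
    for j, i0 in enumerate(events):
        i1 = events[j + 1] if j + 1 < len(events) else len(V)
        # local maximum between this crossing and the next event (or end)
        seg = V[i0:i1]
        below = np.flatnonzero(seg < 0.0)
        if below.size:
            seg = seg[:below[0] + 1]
        if seg.size == 0:
            continue
        k = int(np.argmax(seg))
        peak_idx.append(i0 + k)
        peaks.append(V[i0 + k])
        upstrokes.append(i0)
    peak_idx = np.asarray(peak_idx, dtype=int)
    if stim_window is None:
        stim_window = trace.stim_window
    win = max(stim_window[1] - stim_window[0], trace.dt)
    rate = len(peak_idx) / (win * 1e-3)
    return SpikeFeatures(
        spike_times=t[peak_idx] if len(peak_idx) else np.empty(0),
        peak_V=np.asarray(peaks), peak_index=peak_idx,
        upstroke_index=np.asarray(upstrokes, dtype=int), firing_rate=rate)


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def half_width(trace: SimTrace, spike_index: int,
               features: Optional[SpikeFeatures] = None,
               baseline: str = "threshold") -> float:
    """Width (ms) of one spike at half-height, linearly interpolated.

    The spike height is measured from a baseline to the peak and the
    width is the time between the two crossings of baseline + height/2.
    ``baseline="threshold"`` (default) uses the dV/dt > 20 mV/ms voltage
    threshold of the spike -- the common electrophysiological convention
    of measuring spike amplitude from threshold, and the one that
    reproduces the classic model's reported half-width;
    ``baseline="trough"`` uses the pre-spike trough (minimum voltage in
    the 20 ms preceding the peak).  When the threshold criterion is never
    met on the upstroke, the trough baseline is used as fallback.

    Raises
    ------
    UndefinedWidthError
        If the half-height level is not crossed on both flanks before the
        next spike (or the end of the trace) -- the signature of a
        pseudo-plateau event.
    """
    if baseline not in ("threshold", "trough"):
        raise InputError(f"baseline must be 'threshold' or 'trough', "
                         f"got {baseline!r}")
    f = features or detect_spikes(trace)
    if spike_index >= f.n_spikes:
        raise InputError(f"spike {spike_index} not found "
                         f"({f.n_spikes} spikes in trace)")
    V, t, dt = trace.V, trace.t, trace.dt
    p = f.peak_index[spike_index]
    base = None
    if baseline == "threshold":
        try:
            base = voltage_threshold(trace, spike_index, f)
        except InputError:
            base = None
    if base is None:
        w = max(int(round(HALF_WIDTH_BASELINE_MS / dt)), 1)
        base = float(np.min(V[max(0, p - w):p + 1]))
    level = base + 0.5 * (V[p] - base)
    # rising flank: last crossing of `level` before the peak
    i = p
    while i > 0 and V[i - 1] > level:
        i -= 1
    if i == 0 and V[0] > level:
        raise UndefinedWidthError(
            f"spike {spike_index}: rising flank never crosses half height")
    t_rise = _interp_crossing(t[i - 1], t[i], V[i - 1], V[i], level) \
        if i > 0 else t[0]
    # falling flank: first crossing after the peak, before the next spike
    stop = f.peak_index[spike_index + 1] if spike_index + 1 < f.n_spikes \
        else len(V)
    j = p
    while j + 1 < stop and V[j + 1] > level:
        j += 1
    if j + 1 >= stop:
        raise UndefinedWidthError(
            f"spike {spike_index}: voltage stays above half height "
            f"({level:.2f} mV) until the next event -- plateau-like")
    t_fall = _interp_crossing(t[j], t[j + 1], V[j], V[j + 1], level)
    return float(t_fall - t_rise)


def voltage_threshold(trace: SimTrace, spike_index: int,
                      features: Optional[SpikeFeatures] = None) -> float:
    """Voltage at which dV/dt (central differences) first exceeds 20 mV/ms
    on the upstroke of the given spike."""
    f = features or detect_spikes(trace)
    if spike_index >= f.n_spikes:
        raise InputError(f"spike {spike_index} not found")
    V, dt = trace.V, trace.dt
    p = f.peak_index[spike_index]
    # upstroke starts at the preceding trough
    prev = f.peak_index[spike_index - 1] if spike_index > 0 else 0
    seg0 = prev + int(np.argmin(V[prev:p + 1]))
    dvdt = np.gradient(V[max(seg0 - 1, 0):p + 1], dt)
    rel = np.flatnonzero(dvdt > DVDT_THRESHOLD)
    if rel.size == 0:
        raise InputError(
            f"dV/dt never exceeds {DVDT_THRESHOLD} mV/ms on the upstroke "
            f"of spike {spike_index}")
    return float(V[max(seg0 - 1, 0) + rel[0]])


# ---------------------------------------------------------------------------
# Current threshold (rheobase on a grid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    """Grid rheobase: smallest currents eliciting >= 1 and >= 2 spikes.

    ``grid_step`` doubles as the uncertainty of the estimates.  Fields are
    ``None`` when no grid current elicited the required spikes.
    """

    first_spike_I: Optional[float]
    repetitive_I: Optional[float]
    grid_step: float


def _count_spikes(params, fconfig, amplitude, duration, max_spikes=0):
    proto = StepCurrentProtocol(amplitude=amplitude, duration=duration)
    tr = simulate_hybrid(params, fconfig, proto, max_spikes=max_spikes)
    return detect_spikes(tr).n_spikes, tr


def current_threshold(params: Optional[HHParams] = None,
                      fconfig: Optional[FractionalConfig] = None,
                      I_grid: Optional[Sequence[float]] = None,
                      duration: float = 500.0) -> ThresholdResult:
    """Scan an ascending current grid for the smallest spiking currents.

    Default grid: 1 to 24 in 0.5 steps, 500-ms steps.  Integration stops
    early once two spikes have occurred (the answer for a grid point does
    not depend on anything later), which keeps supra-threshold probes
    cheap.  Returns the smallest grid current with >= 1 spike and the
    smallest with >= 2 spikes ("minimum input current to elicit spiking"
    for the spike-shape analyses).
    """
    params = params or HHParams()
    fconfig = fconfig or FractionalConfig()
    if I_grid is None:
        I_grid = np.arange(1.0, 24.0 + 1e-9, 0.5)
    I_grid = np.asarray(I_grid, dtype=float)
    if I_grid.ndim != 1 or len(I_grid) < 1 or np.any(np.diff(I_grid) <= 0):
        raise InputError("I_grid must be a 1-d ascending sequence")
    step = float(np.min(np.diff(I_grid))) if len(I_grid) > 1 else 0.0
    first_I = None
    rep_I = None
    for I in I_grid:
        n, _ = _count_spikes(params, fconfig, float(I), duration,
                             max_spikes=2)
        if n >= 1 and first_I is None:
            first_I = float(I)
        if n >= 2:
            rep_I = float(I)
            break
    return ThresholdResult(first_spike_I=first_I, repetitive_I=rep_I,
                           grid_step=step)


def minimum_spiking_trace(params: Optional[HHParams] = None,
                          fconfig: Optional[FractionalConfig] = None,
                          I_grid: Optional[Sequence[float]] = None,
                          duration: float = 500.0):
    """Trace at the minimum repetitive-spiking current (for spike shapes).

    Returns ``(I_min, trace)``; the trace covers the full step so the
    second spike can be characterized.
    """
    th = current_threshold(params, fconfig, I_grid, duration)
    if th.repetitive_I is None:
        raise InputError("no grid current elicited repetitive spiking")
    proto = StepCurrentProtocol(amplitude=th.repetitive_I, duration=duration)
    tr = simulate_hybrid(params, fconfig, proto)
    return th.repetitive_I, tr


# ---------------------------------------------------------------------------
# Phase-plane currents
# ---------------------------------------------------------------------------

@dataclass
class PhasePlaneSeries:
    """I_Na vs I_w trajectory aligned with the trace samples.

    I_Na = gNa m^3 h (E_Na - V) (depolarizing positive);
    I_w = potassium + leak + injected currents, same convention; the
    imbalance current is exactly I_Na + I_w, and the "balance line" is
    I_Na + I_w = 0.
    """

    t: np.ndarray
    I_Na: np.ndarray
    I_w: np.ndarray

    @property
    def imbalance(self) -> np.ndarray:
        return self.I_Na + self.I_w


def phase_plane(trace: SimTrace) -> PhasePlaneSeries:
    """Reconstruct the sodium vs (K + leak + input) current trajectory."""
    INa, IK, IL, Iin = trace.currents()
    return PhasePlaneSeries(t=trace.t, I_Na=INa, I_w=IK + IL + Iin)
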