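"""Reproduction workflows: the full-scale characterization protocols.

Each function runs one published characterization end to end with the
package's defaults for that protocol (grids, step sizes, windows) and
returns plain numbers, so the same code path backs both the test suite
and ``scripts/acceptance.py``.

Problem sizes are chosen for a single CPU: persistent-activity runs use
the L1 scheme at dt = 0.01 ms (spike counts there are converged -- they
match dt = 0.005 exactly for the rate protocols), spike-shape
measurements refine to dt = 0.001 ms on short windows after locating the
rheobase on a coarser grid, and the clamp m.s.e. sweep uses every 4th
voltage of the 10-mV grid.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .clamp import MseResult, numeric_vs_analytic_mse
from .errors import DivergenceError, InputError
from .fractional import FractionalConfig, simulate_hybrid
from .hh_core import HHParams, StepCurrentProtocol
from .spikes import (current_threshold, detect_spikes, half_width,
                     voltage_threshold)

ETA_SWEEP = np.round(np.arange(0.2, 1.0 + 1e-9, 0.1), 10)[::-1]

#: reduced voltage set for the dt=0.001 clamp m.s.e. sweeps (every 4th
#: point of the 10-mV grid)
MSE_V_REDUCED = (-100.0, -60.0, -20.0, 20.0, 60.0, 100.0)


def firing_rate(gate: str = "none", eta: float = 1.0, I: float = 18.0,
                duration: float = 1500.0, dt: float = 0.001,
                params: Optional[HHParams] = None):
    """Average firing rate (Hz) over the full stimulus window.

    Returns ``(rate, trace)``.  The persistent-activity protocols use
    duration = 3000 ms (the long stimulation window; fractional spike
    trains decelerate, so the window matters) and dt = 0.01 for
    fractional gates.
    """
    fc = FractionalConfig(fractional_gate=gate, eta=eta, dt=dt)
    proto = StepCurrentProtocol(amplitude=I, duration=duration)
    tr = simulate_hybrid(params, fc, proto)
    feats = detect_spikes(tr)
    return feats.firing_rate, tr


def second_spike_half_width(gate: str = "none", eta: float = 1.0,
                            dt: float = 0.001,
                            I_grid: Optional[Sequence[float]] = None,
                            baseline: str = "threshold"):
    """Half-width (ms) of the 2nd spike at the minimum repetitive-spiking
    current (1-24 nA grid, 0.5 steps, 500-ms steps).

    Returns ``(I_min, width)``.
    """
    fc = FractionalConfig(fractional_gate=gate, eta=eta, dt=dt)
    th = current_threshold(fconfig=fc, I_grid=I_grid)
    if th.repetitive_I is None:
        raise InputError(f"no repetitive spiking found for {gate}, "
                         f"eta={eta}")
    proto = StepCurrentProtocol(amplitude=th.repetitive_I, duration=500.0)
    tr = simulate_hybrid(None, fc, proto)
    f = detect_spikes(tr)
    return th.repetitive_I, half_width(tr, 1, f, baseline=baseline)


def second_spike_voltage_threshold(gate: str, eta: float,
                                   dt_scan: float = 0.01,
                                   dt_measure: float = 0.001,
                                   params: Optional[HHParams] = None):
    """Voltage threshold (dV/dt > 20 mV/ms) of the 2nd spike at rheobase.

    The rheobase is located on the 0.5-nA grid at ``dt_scan`` (falling
    back to dt_scan/2 when the L1 scheme is unstable at the coarse step,
    as for the m gate at eta = 0.3); the threshold itself is measured at
    ``dt_measure`` on a window just covering the first two spikes.
    Returns ``(I_min, threshold_mV)``.

    Raises DivergenceError when the configuration is unstable at every
    scan resolution tried, InputError when no current elicits two spikes.
    """
    fc = FractionalConfig(fractional_gate=gate, eta=eta, dt=dt_scan)
    try:
        th = current_threshold(fconfig=fc)
    except DivergenceError:
        fc = FractionalConfig(fractional_gate=gate, eta=eta,
                              dt=dt_scan / 2.0)
        th = current_threshold(fconfig=fc)
    if th.repetitive_I is None:
        raise InputError(f"no repetitive spiking for {gate}, eta={eta}")
    fcm = FractionalConfig(fractional_gate=gate, eta=eta, dt=dt_measure)
    for dur in (80.0, 300.0):
        proto = StepCurrentProtocol(amplitude=th.repetitive_I, duration=dur)
        tr = simulate_hybrid(params, fcm, proto)
        f = detect_spikes(tr)
        if f.n_spikes >= 2:
            return th.repetitive_I, voltage_threshold(tr, 1, f)
    raise InputError(f"fewer than two spikes at rheobase within 300 ms "
                     f"for {gate}, eta={eta}")


def voltage_threshold_shifts(gate: str,
                             etas: Optional[Sequence[float]] = None):
    """Per-eta voltage thresholds and their shifts relative to eta = 1.

    Returns ``(table, shifts)`` where ``table`` maps eta -> (I_min, V_thr)
    for every stable eta (unstable or non-spiking etas are omitted) and
    ``shifts`` maps eta -> V_thr(eta) - V_thr(1).
    """
    etas = ETA_SWEEP if etas is None else etas
    table = {}
    for eta in etas:
        try:
            table[float(eta)] = second_spike_voltage_threshold(gate,
                                                               float(eta))
        except (DivergenceError, InputError):
            continue
    base = second_spike_voltage_threshold(gate, 1.0)[1] \
        if 1.0 not in table else table[1.0][1]
    shifts = {e: v - base for e, (_, v) in table.items()}
    return table, shifts


def clamp_mse_reduced(gate: str, dt: float = 0.001,
                      compare_every: int = 10,
                      etas: Optional[Sequence[float]] = None) -> MseResult:
    """Numeric-vs-analytic m.s.e. on the reduced voltage set.

    Full eta grid (0.2..1.0 step 0.1) by default x every 4th voltage of
    the 10-mV grid; the comparison grid subsamples the dt grid by
    ``compare_every`` (the error is smooth, so the mean is unchanged to
    well below the reported precision).
    """
    etas = np.sort(ETA_SWEEP) if etas is None else np.asarray(etas, float)
    return numeric_vs_analytic_mse(gate, etas=etas, Vs=MSE_V_REDUCED,
                                   dt=dt, compare_every=compare_every)
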