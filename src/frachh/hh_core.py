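"""Classic Hodgkin-Huxley model: rate functions, steady states, RK4 integration.

The model is the standard squid-axon membrane equation

    C dV/dt = -( g_m (V - E_L) + gK n^4 (V - E_K) + gNa m^3 h (V - E_Na) ) + I

with first-order gating kinetics dx/dt = alpha_x(V) (1 - x) - beta_x(V) x for
x in {n, m, h}.  Everything here is the eta = 1 baseline that the fractional
machinery in :mod:`frachh.fractional` is validated against.

Units
-----
Time in ms, voltage in mV, conductances in mS/cm^2, capacitance in uF/cm^2.
Input currents are taken verbatim from the conventional "nA" labelling of
current steps into 1 cm^2 of membrane; dimensionally they behave as uA/cm^2
(1 uA/cm^2 through 1 uF/cm^2 gives 1 mV/ms), and the model is internally
consistent under that reading.

Sign convention: ionic currents are expressed as contributions to C dV/dt,
so the depolarizing sodium current is I_Na = gNa m^3 h (E_Na - V) > 0 during
the upstroke, and C dV/dt = I_Na + I_K + I_L + I_in holds at every sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DivergenceError, InputError
from . import _kernels

GATES = ("n", "m", "h")

#: Sample times beyond this |V| are rejected as unphysical input.
_V_SANE = 1e6


@dataclass(frozen=True)
class HHParams:
    """Membrane constants and reversal potentials.

    Defaults are the standard values for 1 cm^2 of membrane:
    C = 1 uF, gNa = 120 mS, gK = 36 mS, g_m = 0.3 mS, E_Na = 50 mV,
    E_K = -77 mV, E_L = -54 mV, with the rate functions referenced to
    V0 = -65 mV.
    """

    C: float = 1.0
    gNa_bar: float = 120.0
    gK_bar: float = 36.0
    gm: float = 0.3
    ENa: float = 50.0
    EK: float = -77.0
    EL: float = -54.0
    V0: float = -65.0

    def __post_init__(self):
        if not self.C > 0:
            raise ConfigError(f"capacitance must be positive, got C={self.C}")
        for name in ("gNa_bar", "gK_bar", "gm"):
            if getattr(self, name) < 0:
                raise ConfigError(f"conductance {name} must be >= 0, got "
                                  f"{getattr(self, name)}")


@dataclass(frozen=True)
class GateState:
    """Dimensionless activation/inactivation values (n, m, h)."""

    n: float
    m: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.m, self.h])


@dataclass(frozen=True)
class StepCurrentProtocol:
    """Constant current step: ``amplitude`` from ``onset`` for ``duration`` ms.

    ``amplitude`` uses the conventional "nA" labelling for current into
    1 cm^2 of membrane (dimensionally uA/cm^2; see module docstring).
    """

    amplitude: float
    onset: float = 0.0
    duration: float = 500.0
    total_time: Optional[float] = None

    def __post_init__(self):
        if self.onset < 0:
            raise ConfigError(f"onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        if self.total_time is None:
            object.__setattr__(self, "total_time", self.onset + self.duration)
        elif self.total_time < self.onset + self.duration:
            raise ConfigError(
                f"total_time={self.total_time} shorter than "
                f"onset+duration={self.onset + self.duration}")


@dataclass
class SimTrace:
    """Uniformly sampled simulation output.

    Attributes
    ----------
    t, V, n, m, h : ndarray
        Time grid (ms) and state variables.
    memtrace : ndarray or None
        L1 memory-trace sample per step for the fractional gate; ``None``
        for purely classic runs.
    dt : float
        Grid spacing in ms (after any storage decimation).
    params, protocol : metadata used to reconstruct currents and windows.
    fractional_gate, eta : which gate (if any) evolved fractionally.
    truncation_error_bound : worst-case bound on the neglected memory tail
        when a windowed history was used (None for full memory).
    """

    t: np.ndarray
    V: np.ndarray
    n: np.ndarray
    m: np.ndarray
    h: np.ndarray
    dt: float
    memtrace: Optional[np.ndarray] = None
    params: HHParams = field(default_factory=HHParams)
    protocol: Optional[StepCurrentProtocol] = None
    fractional_gate: Optional[str] = None
    eta: float = 1.0
    truncation_error_bound: Optional[float] = None

    def __len__(self):
        return len(self.t)

    def currents(self):
        """Per-channel currents as contributions to C dV/dt.

        Returns ``(INa, IK, IL, Iin)`` reconstructed from the stored state,
        with I_Na = gNa m^3 h (E_Na - V) etc.
        """
        p = self.params
        INa = p.gNa_bar * self.m ** 3 * self.h * (p.ENa - self.V)
        IK = p.gK_bar * self.n ** 4 * (p.EK - self.V)
        IL = p.gm * (p.EL - self.V)
        if self.protocol is not None:
            pr = self.protocol
            Iin = np.where(
                (self.t >= pr.onset) & (self.t < pr.onset + pr.duration),
                pr.amplitude, 0.0)
        else:
            Iin = np.zeros_like(self.t)
        return INa, IK, IL, Iin

    @property
    def stim_window(self):
        """(start, stop) of the stimulus in ms; full span if unknown."""
        if self.protocol is not None:
            return (self.protocol.onset,
                    self.protocol.onset + self.protocol.duration)
        return (float(self.t[0]), float(self.t[-1]))

    def to_frame(self) -> pd.DataFrame:
        """DataFrame with the canonical column layout of the trace CSV."""
        INa, IK, IL, Iin = self.currents()
        data = {"t_ms": self.t, "V_mV": self.V, "n": self.n, "m": self.m,
                "h": self.h, "INa": INa, "IK": IK, "IL": IL, "Iin": Iin}
        if self.memtrace is not None:
            data["memtrace"] = self.memtrace
        return pd.DataFrame(data)

    def decimate(self, factor: int) -> "SimTrace":
        """Keep every ``factor``-th sample (for storage)."""
        if factor < 1:
            raise ConfigError(f"decimation factor must be >= 1, got {factor}")
        mt = None if self.memtrace is None else self.memtrace[::factor]
        return SimTrace(
            t=self.t[::factor], V=self.V[::factor], n=self.n[::factor],
            m=self.m[::factor], h=self.h[::factor], dt=self.dt * factor,
            memtrace=mt, params=self.params, protocol=self.protocol,
            fractional_gate=self.fractional_gate, eta=self.eta,
            truncation_error_bound=self.truncation_error_bound)


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def _check_V(V):
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)) or np.any(np.abs(V) > _V_SANE):
        raise InputError(f"voltage must be finite, got {V!r}")
    return V


def rate(gate_id: str, kind: str, V):
    """Forward (``alpha``) or backward (``beta``) rate of a gate, per ms.

    The removable singularities of alpha_n (V - V0 = 10) and alpha_m
    (V - V0 = 25) are evaluated through the analytic limit of s/(e^s - 1)
    (equal to 0.1 and 1.0 respectively at the singular voltage).

    Parameters
    ----------
    gate_id : {"n", "m", "h"}
    kind : {"alpha", "beta"}
    V : float or ndarray, mV
    """
    if gate_id not in GATES:
        raise InputError(f"unknown gate {gate_id!r}; expected one of {GATES}")
    if kind not in ("alpha", "beta"):
        raise InputError(f"kind must be 'alpha' or 'beta', got {kind!r}")
    V = _check_V(V)
    u = V - HHParams().V0
    return _rate_u(gate_id, kind, u)


def _rate_u(gate_id, kind, u, V0_shift=None):
    # u = V - V0.  Stable s/expm1(s) form removes the 0/0 singularities.
    if gate_id == "n":
        if kind == "alpha":
            s = 1.0 - 0.1 * u
            return 0.1 * _s_over_expm1(s)
        return 0.125 * np.exp(-u / 80.0)
    if gate_id == "m":
        if kind == "alpha":
            s = 2.5 - 0.1 * u
            return _s_over_expm1(s)
        return 4.0 * np.exp(-u / 18.0)
    if kind == "alpha":
        return 0.07 * np.exp(-u / 20.0)
    return 1.0 / (1.0 + np.exp(3.0 - 0.1 * u))


def _s_over_expm1(s):
    s = np.asarray(s, dtype=float)
    out = np.empty_like(s)
    small = np.abs(s) < 1e-8
    out[small] = 1.0 - 0.5 * s[small]
    with np.errstate(over="ignore"):
        out[~small] = s[~small] / np.expm1(s[~small])
    if out.ndim == 0:
        return float(out)
    return out


def steady_state(V, params: Optional[HHParams] = None) -> GateState:
    """Equilibrium gate values x_inf(V) = alpha/(alpha+beta) at voltage V.

    At the resting reference V = -65 mV this returns
    (n, m, h) = (0.3177, 0.0529, 0.5960) to four decimals, the initial
    conditions used throughout.
    """
    V = _check_V(V)
    V0 = (params or HHParams()).V0
    u = V - V0
    vals = []
    for g in GATES:
        a = _rate_u(g, "alpha", u)
        b = _rate_u(g, "beta", u)
        vals.append(a / (a + b))
    return GateState(n=vals[0], m=vals[1], h=vals[2])


def time_constant(V, gate_id: str, params: Optional[HHParams] = None):
    """Classic relaxation time tau_x(V) = 1/(alpha_x + beta_x), in ms."""
    if gate_id not in GATES:
        raise InputError(f"unknown gate {gate_id!r}")
    V = _check_V(V)
    u = V - (params or HHParams()).V0
    return 1.0 / (_rate_u(gate_id, "alpha", u) + _rate_u(gate_id, "beta", u))


def gate_derivative(V, x, gate_id: str, params: Optional[HHParams] = None):
    """dx/dt = alpha (1 - x) - beta x for one gate (classic kinetics)."""
    u = _check_V(V) - (params or HHParams()).V0
    a = _rate_u(gate_id, "alpha", u)
    b = _rate_u(gate_id, "beta", u)
    return a * (1.0 - x) - b * x


def default_init(params: Optional[HHParams] = None):
    """Default initial condition: V = -65 mV and gates at steady_state(-65).

    This reproduces the reported initial values (0.3177, 0.0529, 0.5960) and
    produces zero voltage change at I = 0 in the classic model.
    """
    p = params or HHParams()
    return -65.0, steady_state(-65.0, p)


# ---------------------------------------------------------------------------
# RK4 integration of the full classic model
# ---------------------------------------------------------------------------

def simulate_classic(params: Optional[HHParams] = None,
                     protocol: Optional[StepCurrentProtocol] = None,
                     init=None, dt: float = 0.001,
                     max_spikes: int = 0) -> SimTrace:
    """Integrate the classic (eta = 1 everywhere) model with 4th-order RK.

    Parameters
    ----------
    params : HHParams, optional
    protocol : StepCurrentProtocol, optional
        Defaults to a zero-amplitude 100-ms step (quiescence check).
    init : (V, GateState), optional
        Defaults to :func:`default_init`.
    dt : float, ms
        Integration and storage step (default 0.001).
    max_spikes : int
        If > 0, stop integration once this many upward 0-mV crossings
        (>= 2 ms apart) have occurred; the returned trace is truncated.
        Used by threshold searches to avoid integrating past the answer.

    Raises
    ------
    ConfigError
        If dt <= 0.
    DivergenceError
        On numerical overflow, naming the first bad time step.
    """
    if not dt > 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    p = params or HHParams()
    proto = protocol or StepCurrentProtocol(amplitude=0.0, duration=100.0)
    if init is None:
        V_init, gs = default_init(p)
    else:
        V_init, gs = init
    n_steps = int(round(proto.total_time / dt))
    V, n, m, h, status, n_done = _kernels.rk4_classic(
        float(V_init), gs.n, gs.m, gs.h, dt, n_steps,
        p.C, p.gNa_bar, p.gK_bar, p.gm, p.ENa, p.EK, p.EL, p.V0,
        proto.amplitude, proto.onset, proto.onset + proto.duration,
        max_spikes, 2.0)
    if status == _kernels.STATUS_NONFINITE:
        raise DivergenceError(
            f"classic integration overflowed at step {n_done} "
            f"(t = {n_done * dt:.6g} ms)", dt=dt, step=n_done,
            time_ms=n_done * dt)
    end = n_done + 1
    t = np.arange(end) * dt
    return SimTrace(t=t, V=V[:end], n=n[:end], m=m[:end], h=h[:end],
                    dt=dt, params=p, protocol=proto)
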