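"""Classification of emergent spiking patterns and (I, eta) phase diagrams.

Six pattern classes arise when one gate follows power-law kinetics under
constant current injection:

- RS  (resting state): no spikes, or a single onset spike;
- TS  (tonic spiking): sustained repetitive firing;
- PS  (phasic spiking): a few spikes early, then silence;
- MMO (mixed-mode oscillations): isolated spikes separated by
  sub-threshold oscillations;
- SWB (square-wave bursting): groups of spikes separated by oscillatory
  silent phases;
- PPB (pseudo-plateau bursting): long-lasting depolarized events
  (pituitary- or cardiac-like action potentials).

The decision rules below are a documented, deterministic operationalization
of this taxonomy (the class definitions are qualitative); the numeric
knobs live in :class:`ClassifierConfig` and were fixed against the five
reference (gate, eta, I) exemplars of each non-trivial class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import DivergenceError, InputError, UndefinedWidthError
from .fractional import FractionalConfig, simulate_hybrid
from .hh_core import HHParams, SimTrace, StepCurrentProtocol
from .spikes import SpikeFeatures, detect_spikes, half_width

PATTERNS = ("RS", "PS", "TS", "MMO", "SWB", "PPB")


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric thresholds of the pattern rules (all documented knobs).

    osc_prominence : minimal prominence (mV) of a sub-threshold peak.
    osc_max_V : sub-threshold peaks must stay below this (mV).
    osc_min_sep_ms : minimal separation between oscillation peaks.
    spike_mask_ms : half-width of the mask around spike peaks when
        searching for oscillations.
    short_window_ms / silent_after_ms : phasic-spiking windows (all
        spikes before the first, none after the second).
    intra_burst_isi_ms / inter_burst_isi_ms : burst grouping bounds.
    plateau_level_mV / plateau_min_ms : supra-threshold plateau rule
        for pseudo-plateau events.
    """

    osc_prominence: float = 1.0
    osc_max_V: float = -20.0
    osc_min_sep_ms: float = 2.0
    spike_mask_ms: float = 3.0
    short_window_ms: float = 500.0
    silent_after_ms: float = 1000.0
    long_window_ms: float = 1000.0
    intra_burst_isi_ms: float = 60.0
    inter_burst_isi_ms: float = 75.0
    plateau_level_mV: float = -20.0
    plateau_min_ms: float = 20.0
    mmo_gap_fraction: float = 0.5
    ripple_level_mV: float = -35.0
    ripple_min_count: int = 3


@dataclass
class PatternLabel:
    """One of the six pattern labels plus its supporting evidence."""

    label: str
    evidence: dict = field(default_factory=dict)
    warning: Optional[str] = None

    def __str__(self):
        return self.label


def detect_subthreshold_oscillations(trace: SimTrace,
                                     features: Optional[SpikeFeatures] = None,
                                     config: Optional[ClassifierConfig]
                                     = None) -> np.ndarray:
    """Times (ms) of sub-threshold oscillation peaks.

    Local maxima with prominence >= 1 mV and peak voltage < -20 mV,
    at least 2 ms apart, outside +-3 ms masks around spike peaks.
    """
    cfg = config or ClassifierConfig()
    f = features or detect_spikes(trace)
    dist = max(int(round(cfg.osc_min_sep_ms / trace.dt)), 1)
    peaks, _ = find_peaks(trace.V, prominence=cfg.osc_prominence,
                          distance=dist, height=(None, cfg.osc_max_V))
    tp = trace.t[peaks]
    if f.n_spikes:
        near = np.min(np.abs(tp[:, None] - f.spike_times[None, :]), axis=1)
        tp = tp[near > cfg.spike_mask_ms]
    return tp


def _plateau_spans(trace, features, cfg):
    """Per-spike duration (ms) the voltage stays above the plateau level
    after the peak, and whether the half-width is undefined."""
    spans = []
    undefined = []
    V, dt = trace.V, trace.dt
    for i in range(features.n_spikes):
        p = features.peak_index[i]
        stop = features.peak_index[i + 1] if i + 1 < features.n_spikes \
            else len(V)
        above = V[p:stop] > cfg.plateau_level_mV
        first_below = np.argmin(above) if not above.all() else len(above)
        spans.append(first_below * dt)
        try:
            half_width(trace, i, features)
            undefined.append(False)
        except UndefinedWidthError:
            undefined.append(True)
        except InputError:
            undefined.append(True)
    return np.asarray(spans), np.asarray(undefined, dtype=bool)


def _burst_structure(spike_times, cfg):
    """Group spikes into bursts split at ISIs > inter_burst_isi_ms."""
    if len(spike_times) == 0:
        return []
    isis = np.diff(spike_times)
    cuts = np.flatnonzero(isis > cfg.inter_burst_isi_ms)
    bursts = np.split(spike_times, cuts + 1)
    return bursts


def classify(trace: SimTrace, stim_window=None,
             config: Optional[ClassifierConfig] = None) -> PatternLabel:
    """Assign one of the six pattern labels to a voltage trace.

    Fractional spike trains are non-stationary (the memory trace builds
    up over hundreds of milliseconds), so the rules weigh the short-term
    (< 500 ms) and long-term (> 1000 ms) windows separately and are
    applied in priority order:

    1. PPB: any spike with an undefined half-width, or with the voltage
       staying above -20 mV for >= 20 ms after the peak.
    2. RS: at most one spike in total.
    3. PS: >= 2 spikes, all within the first 500 ms of stimulation and
       none after 1000 ms.
    4. SWB: in the long-term window the spikes group into >= 2 bursts
       (split at ISIs > 75 ms), at least one burst has >= 2 spikes at
       intra-burst ISIs < 60 ms, and >= 1 silent gap contains a
       sub-threshold oscillation.
    5. MMO: at least half of the long-term inter-spike gaps contain a
       sub-threshold oscillation (spikes not grouped into bursts).
    6. TS otherwise; a warning flag marks conflicting evidence (some but
       too few oscillation-bearing gaps).
    """
    cfg = config or ClassifierConfig()
    if stim_window is None:
        stim_window = trace.stim_window
    t_on, t_off = stim_window
    if t_off - t_on < 1000.0:
        raise InputError(
            "pattern classification needs >= 1000 ms of stimulation "
            f"(got {t_off - t_on:.0f} ms)")
    f = detect_spikes(trace, stim_window=stim_window)
    osc = detect_subthreshold_oscillations(trace, f, cfg)
    spans, undef = _plateau_spans(trace, f, cfg) if f.n_spikes else \
        (np.empty(0), np.empty(0, dtype=bool))
    st = f.spike_times
    t_long = t_on + cfg.long_window_ms
    late = st[st > t_long]
    late_bursts = _burst_structure(late, cfg)
    # long-term inter-spike gaps: right edge inside the long window
    gaps = [(st[i], st[i + 1]) for i in range(len(st) - 1)
            if st[i + 1] > t_long]
    gaps_with_osc = sum(bool(np.any((osc > a) & (osc < b)))
                        for a, b in gaps)
    ev = {
        "n_spikes": int(f.n_spikes),
        "n_spikes_short": int(np.sum(st <= t_on + cfg.short_window_ms)),
        "n_spikes_late": int(len(late)),
        "n_oscillations": int(len(osc)),
        "n_late_bursts": len(late_bursts),
        "late_burst_sizes": [len(b) for b in late_bursts],
        "n_long_gaps": len(gaps),
        "n_gaps_with_osc": int(gaps_with_osc),
        "max_plateau_ms": float(spans.max()) if spans.size else 0.0,
        "n_undefined_width": int(undef.sum()),
        "firing_rate": float(f.firing_rate),
    }

    # 1. pseudo-plateau bursting
    if f.n_spikes and (undef.any() or (spans >= cfg.plateau_min_ms).any()):
        ev["ppb_subtype"] = _ppb_subtype(trace, f, cfg)
        return PatternLabel("PPB", ev)
    # 2. resting state
    if f.n_spikes <= 1:
        return PatternLabel("RS", ev)
    # 3. phasic spiking
    if np.all(st <= t_on + cfg.short_window_ms) and \
            not np.any(st > t_on + cfg.silent_after_ms):
        return PatternLabel("PS", ev)
    # 4. square-wave bursting (long-term burst structure)
    multi = [b for b in late_bursts if len(b) >= 2]
    if len(late_bursts) >= 2 and multi:
        intra_ok = all(np.all(np.diff(b) < cfg.intra_burst_isi_ms)
                       for b in multi)
        burst_gaps = [(late_bursts[i][-1], late_bursts[i + 1][0])
                      for i in range(len(late_bursts) - 1)]
        osc_in_gap = sum(bool(np.any((osc > a) & (osc < b)))
                         for a, b in burst_gaps)
        if intra_ok and osc_in_gap >= 1:
            return PatternLabel("SWB", ev)
    # 5. mixed-mode oscillations (oscillations between most late spikes)
    if gaps and gaps_with_osc >= cfg.mmo_gap_fraction * len(gaps):
        return PatternLabel("MMO", ev)
    # 6. tonic spiking
    warning = None
    if gaps_with_osc:
        warning = (f"{gaps_with_osc}/{len(gaps)} long-term gaps contain "
                   "sub-threshold oscillations (below the MMO fraction); "
                   "fell back to TS")
    return PatternLabel("TS", ev, warning=warning)


def _ppb_subtype(trace, features, cfg):
    """Pituitary- vs cardiac-type plateau.

    Pituitary-type events carry repeated high-voltage ripples on the
    decaying plateau (local maxima above -35 mV that are not spike
    peaks); cardiac-type plateaus are smooth.
    """
    V = trace.V
    peaks, _ = find_peaks(V, prominence=cfg.osc_prominence,
                          height=cfg.ripple_level_mV)
    tp = trace.t[peaks]
    near = np.min(np.abs(tp[:, None] - features.spike_times[None, :]),
                  axis=1) if features.n_spikes else np.full(len(tp), np.inf)
    n_ripples = int(np.sum(near > cfg.spike_mask_ms))
    return "pituitary" if n_ripples >= cfg.ripple_min_count else "cardiac"


# ---------------------------------------------------------------------------
# (I, eta) phase diagrams
# ---------------------------------------------------------------------------

UNSTABLE = "unstable"


@dataclass
class PhaseDiagram:
    """Label matrix over an (I, eta) grid (rows = currents).

    Cells where the integration diverged carry the distinct label
    ``"unstable"`` rather than being silently dropped.
    """

    I_grid: np.ndarray
    eta_grid: np.ndarray
    labels: np.ndarray          # dtype=object, shape (len(I), len(eta))
    evidence: np.ndarray        # dicts, same shape

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.labels, index=self.I_grid,
                            columns=self.eta_grid)


def sweep_phase_diagram(gate_id: str,
                        I_grid=None, eta_grid=None,
                        duration: float = 1500.0, dt: float = 0.01,
                        params: Optional[HHParams] = None,
                        config: Optional[ClassifierConfig] = None,
                        progress: bool = False) -> PhaseDiagram:
    """Classify every cell of an (I, eta) grid for one fractional gate.

    Defaults: I = 0..20 nA step 1, eta = 0.2..1.0 step 0.1, 1500 ms of
    stimulation at dt = 0.01 ms with full L1 memory.
    """
    I_grid = np.arange(0.0, 20.0 + 1e-9, 1.0) if I_grid is None \
        else np.asarray(I_grid, float)
    eta_grid = np.round(np.arange(0.2, 1.0 + 1e-9, 0.1), 10) \
        if eta_grid is None else np.asarray(eta_grid, float)
    labels = np.empty((len(I_grid), len(eta_grid)), dtype=object)
    evidence = np.empty_like(labels)
    for j, eta in enumerate(eta_grid):
        fc = FractionalConfig(fractional_gate=gate_id, eta=float(eta), dt=dt)
        for i, I in enumerate(I_grid):
            proto = StepCurrentProtocol(amplitude=float(I),
                                        duration=duration)
            try:
                tr = simulate_hybrid(params, fc, proto)
                lab = classify(tr, config=config)
                labels[i, j] = lab.label
                evidence[i, j] = lab.evidence
            except DivergenceError as err:
                labels[i, j] = UNSTABLE
                evidence[i, j] = {"error": str(err),
                                  "time_ms": err.time_ms}
            if progress:
                print(f"eta={eta:.1f} I={I:g}: {labels[i, j]}")
    return PhaseDiagram(I_grid=I_grid, eta_grid=eta_grid, labels=labels,
                        evidence=evidence)
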