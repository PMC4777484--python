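"""Configuration loading and trace/summary file formats.

Config files are JSON with four optional blocks -- ``model``,
``fractional``, ``protocol``, ``output`` -- plus ``log_level``.  The empty
object ``{}`` yields exactly the standard defaults (classic parameters,
dt = 0.001 ms, V init -65 mV).  Unknown keys are rejected with their
location so typos cannot silently fall back to defaults.

Trace CSVs use the fixed column order ``t_ms,V_mV,n,m,h,INa,IK,IL,Iin``
(plus ``memtrace`` for fractional runs) and are written at 17 significant
digits, so a write/read round trip is bitwise exact.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .clamp import VoltageClampProtocol
from .errors import ConfigError, InputError
from .fractional import FractionalConfig
from .hh_core import HHParams, SimTrace, StepCurrentProtocol

TRACE_COLUMNS = ["t_ms", "V_mV", "n", "m", "h", "INa", "IK", "IL", "Iin"]
FLOAT_FORMAT = "%.17g"


@dataclass
class RunConfig:
    """Fully validated and defaulted run configuration."""

    model: HHParams = field(default_factory=HHParams)
    fractional: FractionalConfig = field(default_factory=FractionalConfig)
    protocol: Union[StepCurrentProtocol, VoltageClampProtocol] = \
        field(default_factory=lambda: StepCurrentProtocol(
            amplitude=0.0, duration=100.0))
    decimation: int = 1
    output_path: Optional[str] = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        proto = vars(self.protocol).copy()
        proto["type"] = "clamp" if isinstance(self.protocol,
                                              VoltageClampProtocol) \
            else "step"
        return {
            "model": vars(self.model).copy(),
            "fractional": {
                "gate": self.fractional.fractional_gate,
                "eta": self.fractional.eta,
                "dt": self.fractional.dt,
                "truncation": self.fractional.truncation,
                "divergence_bound": self.fractional.divergence_bound,
            },
            "protocol": proto,
            "output": {"decimation": self.decimation,
                       "path": self.output_path},
            "log_level": self.log_level,
        }


_MODEL_KEYS = {"C", "gNa_bar", "gK_bar", "gm", "ENa", "EK", "EL", "V0"}
_FRAC_KEYS = {"gate", "eta", "dt", "truncation", "divergence_bound"}
_STEP_KEYS = {"type", "amplitude", "onset", "duration", "total_time"}
_CLAMP_KEYS = {"type", "hold_V", "hold_duration", "target_V",
               "target_duration"}
_OUTPUT_KEYS = {"decimation", "path"}
_TOP_KEYS = {"model", "fractional", "protocol", "output", "log_level"}


def _reject_unknown(d, allowed, where):
    for k in d:
        if k not in allowed:
            raise ConfigError(
                f"unknown key {k!r} at {where}; allowed: "
                f"{sorted(allowed)}")


def _number(d, key, where, default):
    v = d.get(key, default)
    if v is None:
        return None
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{where}.{key} must be a number, got {v!r}")
    return float(v)


def parse_config(data: dict) -> RunConfig:
    """Validate a config dictionary into a :class:`RunConfig`."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    _reject_unknown(data, _TOP_KEYS, "top level")
    mb = data.get("model", {})
    _reject_unknown(mb, _MODEL_KEYS, "model")
    defaults = HHParams()
    model = HHParams(**{k: _number(mb, k, "model", getattr(defaults, k))
                        for k in _MODEL_KEYS})
    fb = data.get("fractional", {})
    _reject_unknown(fb, _FRAC_KEYS, "fractional")
    trunc = fb.get("truncation", "full")
    if isinstance(trunc, float) and trunc.is_integer():
        trunc = int(trunc)
    frac = FractionalConfig(
        fractional_gate=fb.get("gate", "none"),
        eta=_number(fb, "eta", "fractional", 1.0),
        dt=_number(fb, "dt", "fractional", 0.001),
        truncation=trunc,
        divergence_bound=_number(fb, "divergence_bound", "fractional", 10.0))
    pb = data.get("protocol", {})
    ptype = pb.get("type", "step")
    if ptype == "step":
        _reject_unknown(pb, _STEP_KEYS, "protocol")
        proto = StepCurrentProtocol(
            amplitude=_number(pb, "amplitude", "protocol", 0.0),
            onset=_number(pb, "onset", "protocol", 0.0),
            duration=_number(pb, "duration", "protocol", 100.0),
            total_time=_number(pb, "total_time", "protocol", None))
    elif ptype == "clamp":
        _reject_unknown(pb, _CLAMP_KEYS, "protocol")
        proto = VoltageClampProtocol(
            hold_V=_number(pb, "hold_V", "protocol", 0.0),
            hold_duration=_number(pb, "hold_duration", "protocol", 25.0),
            target_V=_number(pb, "target_V", "protocol", 0.0),
            target_duration=_number(pb, "target_duration", "protocol",
                                    110.0))
    else:
        raise ConfigError(f"protocol.type must be 'step' or 'clamp', "
                          f"got {ptype!r}")
    ob = data.get("output", {})
    _reject_unknown(ob, _OUTPUT_KEYS, "output")
    dec = ob.get("decimation", 1)
    if not (isinstance(dec, int) and not isinstance(dec, bool) and dec >= 1):
        raise ConfigError(f"output.decimation must be an integer >= 1, "
                          f"got {dec!r}")
    log_level = data.get("log_level", "INFO")
    if not isinstance(log_level, str):
        raise ConfigError("log_level must be a string")
    return RunConfig(model=model, fractional=frac, protocol=proto,
                     decimation=dec, output_path=ob.get("path"),
                     log_level=log_level)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration file."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise InputError(f"config file not found: {path}")
    except json.JSONDecodeError as err:
        raise ConfigError(f"malformed JSON in {path}: {err}")
    return parse_config(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Trace CSV
# ---------------------------------------------------------------------------

def write_trace(trace: SimTrace, path, decimation: int = 1) -> None:
    """Write a trace CSV (every ``decimation``-th sample, 17 sig digits)."""
    tr = trace.decimate(decimation) if decimation > 1 else trace
    tr.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace(path) -> SimTrace:
    """Read a trace CSV back into a :class:`SimTrace`.

    Model parameters and protocol are not stored in the CSV; the returned
    trace carries defaults for those and is suitable for spike metrics and
    phase-plane analysis (which recompute currents from V and the gates
    when metadata is present, and use the stored columns otherwise).
    """
    try:
        # round_trip parsing keeps the 17-digit write/read cycle bitwise
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise InputError(f"malformed trace CSV {path}: {err}")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            f"trace CSV {path} is missing columns {missing} (line 1)")
    numeric = df[TRACE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise InputError(
            f"trace CSV {path}: non-numeric or missing value at line "
            f"{row + 2}")  # +1 header, +1 one-based
    df[TRACE_COLUMNS] = numeric
    t = df["t_ms"].to_numpy()
    if len(t) < 2:
        raise InputError(f"trace CSV {path} has fewer than two samples")
    dt = float(t[1] - t[0])
    mt = df["memtrace"].to_numpy() if "memtrace" in df.columns else None
    return SimTrace(t=t, V=df["V_mV"].to_numpy(), n=df["n"].to_numpy(),
                    m=df["m"].to_numpy(), h=df["h"].to_numpy(), dt=dt,
                    memtrace=mt)


def write_summary(obj: dict, path) -> None:
    """Write a JSON summary (numpy types converted to plain Python)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def provenance_record(config: RunConfig, wall_time_s: float) -> dict:
    """Reproducibility record written beside CLI outputs."""
    import frachh
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "frachh_version": frachh.__version__,
        "numpy_version": np.__version__,
        "wall_time_s": wall_time_s,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
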