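"""Trace and report I/O plus configuration loading.

Traces travel as CSV with the canonical schema (see :mod:`pvloop.trace`);
analysis results as schema-versioned JSON with units recorded next to the
numbers; run configuration as a YAML file with ``impedance``, ``heart``,
``controller`` and ``protocol`` sections whose keys map one-to-one onto the
corresponding parameter dataclasses.  Unknown config keys are rejected by
name.  NaN metrics are serialized as JSON null alongside their quality
flags (JSON has no NaN literal).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .analysis import RampResult
from .controller import ControllerConfig, RampProtocol
from .heart import HeartParams
from .impedance import ImpedanceParams
from .trace import TRACE_COLUMNS, VALID_PHASES, WaveformTrace

REPORT_SCHEMA_VERSION = 1


class TraceError(ValueError):
    """Base class for trace-format errors."""

    code = "E_TRACE"


class MissingColumnError(TraceError):
    code = "E_MISSING_COLUMN"


class NonMonotoneTimeError(TraceError):
    code = "E_NONMONOTONE_TIME"


class UnknownPhaseError(TraceError):
    code = "E_UNKNOWN_PHASE"


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""

    code = "E_CONFIG"


def write_trace(trace: WaveformTrace, path: "str | Path") -> None:
    """Write a trace as CSV with the canonical header."""
    trace.data.to_csv(path, index=False, float_format="%.9g")


def read_trace(path: "str | Path") -> WaveformTrace:
    """Read and validate a trace CSV.

    Raises :class:`MissingColumnError`, :class:`NonMonotoneTimeError` or
    :class:`UnknownPhaseError` — each a distinct, named condition.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"trace file {path} is missing column(s): {missing}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotoneTimeError(f"trace file {path}: time column is not strictly increasing")
    bad = set(np.unique(df["phase"].to_numpy())) - set(VALID_PHASES)
    if bad:
        raise UnknownPhaseError(f"trace file {path}: unknown phase code(s) {sorted(bad)}")
    return WaveformTrace(df)


# --- report ---------------------------------------------------------------

_UNITS = {
    "Ees": "mmHg/mL",
    "V0_fit": "mL",
    "espvr_r2": "unitless",
    "dpdt_max": "mmHg/s",
    "dpdt_min": "mmHg/s",
    "p_max": "mmHg",
    "edv": "mL",
    "esv": "mL",
    "sv": "mL",
    "stroke_work": "mmHg*mL",
    "tau": "ms",
    "ed_point": "(mL, mmHg)",
    "es_point": "(mL, mmHg)",
    "preload_level": "mmHg",
    "edpvr.A": "mmHg",
    "edpvr.B": "1/mL",
    "edpvr.V_ref": "mL",
    "edpvr.slope": "mmHg/mL",
    "edpvr.intercept": "mmHg",
    "levels": "mmHg",
}


def _jsonify(x: Any) -> Any:
    """Recursively convert to JSON-safe values; NaN/inf become null."""
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, (np.floating, float)):
        xf = float(x)
        return xf if math.isfinite(xf) else None
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def report_dict(result: RampResult) -> dict:
    """Schema-versioned dict form of a :class:`RampResult`."""
    beats = []
    for m in result.beats:
        d = dataclasses.asdict(m)
        if math.isnan(m.tau) and not any(f.startswith("tau") for f in m.flags):
            d["flags"] = list(m.flags) + ["tau: not computed"]
        beats.append(d)
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "units": _UNITS,
        "espvr": {
            "Ees": result.Ees,
            "V0_fit": result.V0_fit,
            "r2": result.espvr_r2,
            "es_method": result.es_method,
        },
        "edpvr": dataclasses.asdict(result.edpvr) if result.edpvr is not None else None,
        "levels": result.levels,
        "n_beats_used": result.n_beats_used,
        "settle_beats": result.settle_beats,
        "tau_method": result.tau_method,
        "beats": beats,
    }
    return _jsonify(doc)


def write_report(result: RampResult, path: "str | Path") -> None:
    """Write the analysis report as JSON (units beside every number)."""
    with open(path, "w") as fh:
        json.dump(report_dict(result), fh, indent=2, allow_nan=False)
        fh.write("\n")


# --- configuration --------------------------------------------------------

@dataclass
class RunConfig:
    """Validated top-level configuration for an end-to-end run."""

    impedance: ImpedanceParams = field(default_factory=ImpedanceParams)
    heart: HeartParams = field(default_factory=HeartParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    protocol: RampProtocol = field(default_factory=RampProtocol)
    seed: int | None = None
    out: str | None = None
    log_level: str = "INFO"


_SECTIONS = {
    "impedance": ImpedanceParams,
    "heart": HeartParams,
    "controller": ControllerConfig,
    "protocol": RampProtocol,
}
_TOP_KEYS = set(_SECTIONS) | {"seed", "out", "log_level"}


def _build_section(name: str, cls: type, payload: dict) -> Any:
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section '{name}' "
            f"(valid: {sorted(fields)})"
        )
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config section '{name}': {exc}") from exc


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping at top level")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level config key(s) {sorted(unknown)} (valid: {sorted(_TOP_KEYS)})"
        )
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        payload = raw.get(name) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build_section(name, cls, payload)
    cfg = RunConfig(**kwargs)
    cfg.seed = raw.get("seed")
    cfg.out = raw.get("out")
    cfg.log_level = raw.get("log_level", "INFO")
    if cfg.seed is not None:
        cfg.heart = dataclasses.replace(cfg.heart, seed=int(cfg.seed))
    return cfg
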