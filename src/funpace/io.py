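"""Sweep-table I/O and configuration loading.

The on-disk format is a plain TSV with ``#key=value`` metadata header lines::

    #dt=0.5
    #unit=pA/pF
    #mode=whole_cell
    #condition=control
    time_ms<TAB>sweep_id<TAB>value
    0<TAB>0<TAB>-1.234 ...

Required metadata keys are ``dt``, ``unit`` and ``mode``.  The voltage
protocol, when present, is carried as one JSON list of epoch lists under
``#epochs=`` (one entry per sweep).  Values are written with 9 significant
digits so write -> read round-trips samples to better than 1e-9 relative.
Decimal points only; the reader/writer are locale-independent.

Configuration files are TOML (parsed with the standard library); unknown
keys are rejected with the offending key path in the message.
"""

from __future__ import annotations

import json
import logging
import tomllib
from typing import Optional

import numpy as np

from .traces import Epoch, FormatError, Recording, Sweep, Trace

log = logging.getLogger("funpace")

_REQUIRED_META = ("dt", "unit", "mode")


def _epoch_to_obj(e: Epoch) -> dict:
    d = {"label": e.label, "duration": e.duration}
    if e.level is not None:
        d["level"] = e.level
    else:
        d["ramp"] = list(e.ramp)
    return d


def _epoch_from_obj(d: dict) -> Epoch:
    return Epoch(label=d.get("label", ""), duration=d["duration"],
                 level=d.get("level"),
                 ramp=tuple(d["ramp"]) if "ramp" in d else None)


def write_sweep_table(recording: Recording, path) -> None:
    """Write a Recording to the sweep-table TSV format."""
    if not recording.sweeps:
        raise FormatError("cannot write a Recording with 0 sweeps")
    dt = recording.dt
    unit = recording.unit
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#dt={dt!r}\n")
        fh.write(f"#unit={unit}\n")
        fh.write(f"#mode={recording.mode}\n")
        if recording.condition:
            fh.write(f"#condition={recording.condition}\n")
        if recording.capacitance is not None:
            fh.write(f"#capacitance={recording.capacitance!r}\n")
        if recording.temperature:
            fh.write(f"#temperature={recording.temperature}\n")
        for key, val in recording.meta.items():
            fh.write(f"#{key}={val}\n")
        if any(sw.epochs for sw in recording.sweeps):
            epochs = [[_epoch_to_obj(e) for e in sw.epochs]
                      for sw in recording.sweeps]
            fh.write(f"#epochs={json.dumps(epochs)}\n")
        fh.write("time_ms\tsweep_id\tvalue\n")
        for sid, sw in enumerate(recording.sweeps):
            t = sw.response.times
            for ti, vi in zip(t, sw.response.samples):
                fh.write(f"{ti:.9g}\t{sid}\t{vi:.9g}\n")
    log.debug("wrote %d sweeps to %s", len(recording.sweeps), path)


def read_sweep_table(path) -> Recording:
    """Read a sweep-table TSV back into a Recording.

    Raises
    ------
    FormatError
        On missing required metadata or a non-uniform time step
        (relative deviation from the header dt above 1e-6).
    """
    meta: dict = {}
    rows_t: list = []
    rows_id: list = []
    rows_v: list = []
    with open(path, "r", encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"malformed metadata line: {line!r}")
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols[:3] != ["time_ms", "sweep_id", "value"]:
                    raise FormatError(f"unexpected column header: {cols}")
                header_seen = True
                continue
            t_s, i_s, v_s = line.split("\t")
            rows_t.append(float(t_s))
            rows_id.append(int(i_s))
            rows_v.append(float(v_s))
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"missing required metadata key #{key}=")
    dt = float(meta["dt"])
    unit = meta["unit"]
    if not rows_t:
        raise FormatError("no data rows")

    t = np.asarray(rows_t)
    sid = np.asarray(rows_id)
    v = np.asarray(rows_v)
    epochs_meta = None
    if "epochs" in meta:
        epochs_meta = json.loads(meta["epochs"])

    sweeps = []
    for k, s in enumerate(sorted(set(sid.tolist()))):
        sel = sid == s
        ts, vs = t[sel], v[sel]
        if ts.size >= 2:
            steps = np.diff(ts)
            if np.any(np.abs(steps - dt) > 1e-6 * dt):
                raise FormatError(
                    f"non-uniform time step in sweep {s}: "
                    f"max deviation {np.abs(steps - dt).max():g} ms")
        trace = Trace(t0=float(ts[0]), dt=dt, samples=vs, unit=unit)
        epochs = []
        if epochs_meta is not None:
            epochs = [_epoch_from_obj(d) for d in epochs_meta[k]]
        sweeps.append(Sweep(epochs=epochs, response=trace))

    known = {"dt", "unit", "mode", "condition", "capacitance", "temperature",
             "epochs", "filter", "seed"}
    extra = {k: v for k, v in meta.items() if k not in known}
    cap = float(meta["capacitance"]) if "capacitance" in meta else None
    return Recording(sweeps=sweeps, condition=meta.get("condition", ""),
                     capacitance=cap, mode=meta["mode"],
                     temperature=meta.get("temperature", ""), meta=extra)


# ---------------------------------------------------------------------------
# configuration

class ConfigError(ValueError):
    """Raised when a config file violates the schema."""


_MISSING = object()

# section -> key -> (type, default); _MISSING marks a required key
CONFIG_SCHEMA = {
    "simulate_ap": {
        "seed": (int, _MISSING),
        "n_cycles": (int, 10),
        "mdp": (float, -60.0),
        "top": (float, -45.0),
        "peak": (float, 25.0),
        "apd": (float, 150.0),
        "edd": (float, 0.094),
        "rate": (float, None),       # optional: prescribe-rate mode
        "noise_sd": (float, 0.5),
        "dt": (float, 0.5),
    },
    "simulate_clamp": {
        "seed": (int, _MISSING),
        "protocol": (str, "two_pulse_train"),
        "camp": (float, 0.0),
        "tmyx": (float, 0.0),
        "mode": (str, "whole_cell"),
        "noise_sd": (float, 0.3),
        "dt": (float, 0.5),
    },
    "hill": {
        "ymax": (float, None),
        "doses": (list, None),
    },
}


def load_config(path) -> dict:
    """Load and validate a TOML configuration file.

    Returns a nested mapping with defaults filled in.  Unknown sections or
    keys raise :class:`ConfigError` naming the offending key path.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out: dict = {}
    for section, content in raw.items():
        if section not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ConfigError(f"[{section}] must be a table")
        schema = CONFIG_SCHEMA[section]
        for key in content:
            if key not in schema:
                raise ConfigError(f"unknown config key {section}.{key}")
        sec_out = {}
        for key, (typ, default) in schema.items():
            if key in content:
                val = content[key]
                if typ is float and isinstance(val, int):
                    val = float(val)
                if typ is not list and not isinstance(val, typ) and val is not None:
                    raise ConfigError(
                        f"config key {section}.{key} must be {typ.__name__}")
                sec_out[key] = val
            elif default is _MISSING:
                raise ConfigError(f"missing required config key {section}.{key}")
            else:
                sec_out[key] = default
        if section == "hill" and sec_out.get("doses") is not None:
            doses = sec_out["doses"]
            if any((not isinstance(d, (int, float))) or d <= 0 for d in doses):
                raise ConfigError("config key hill.doses must be positive numbers")
        out[section] = sec_out
    return out


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr at the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper()))
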