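"""Delimited-text trace I/O, run configuration, and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError
from .trace import GRID_DT, Trace

TRACE_COLUMNS = ("time_ms", "vm_mV")


def write_trace(trace: Trace, path):
    """Write a trace as CSV with header ``time_ms,vm_mV`` on the 0.1 ms grid."""
    df = pd.DataFrame({"time_ms": trace.t, "vm_mV": trace.vm})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(path) -> Trace:
    """Read a delimited trace, validating grid uniformity and finiteness.

    Accepts both LF and CRLF files.  A non-uniform time grid or any
    non-finite sample is rejected with the offending line number.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as delimited text: {exc}") from exc
    if list(df.columns[:2]) != list(TRACE_COLUMNS):
        raise FormatError(
            f"{path}: expected header {','.join(TRACE_COLUMNS)}, "
            f"got {','.join(map(str, df.columns[:2]))}")
    t = df["time_ms"].to_numpy(dtype=float)
    v = df["vm_mV"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(v)))
    if bad.size:
        raise FormatError(f"{path}: non-finite value at line {bad[0] + 2}")
    dt = np.diff(t)
    off = np.flatnonzero(np.abs(dt - GRID_DT) > 1e-6)
    if off.size:
        raise FormatError(
            f"{path}: non-uniform grid at line {off[0] + 3} "
            f"(step {dt[off[0]]:.6g} ms, expected {GRID_DT} ms)")
    return Trace(vm=v, dt=GRID_DT, meta={"source": str(path)})


def write_table(rows, columns, path):
    """Write a simple delimited table (list of rows) as CSV."""
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)


# ---------------------------------------------------------------- config files
def load_config(path) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid configuration syntax: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def resolve_config(defaults: dict, file_cfg: dict | None, cli_cfg: dict | None) -> dict:
    """Layer configuration: defaults < file < CLI flags (None values skipped)."""
    out = dict(defaults)
    for layer in (file_cfg or {}, cli_cfg or {}):
        for k, v in layer.items():
            if k not in defaults:
                raise ConfigError(f"unknown configuration field {k!r}")
            if v is not None:
                out[k] = v
    return out


# -------------------------------------------------------------------- manifest
def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(path, command: str, config: dict, seed,
                   inputs=(), outputs=()):
    """Write the run manifest (resolved config, seed, input digests) as JSON."""
    from . import __version__
    manifest = {
        "tool": "paceopt",
        "version": __version__,
        "formulation_id": "paceopt-hipsc-v1",
        "command": command,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
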