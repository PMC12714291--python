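"""Plain-text recording exchange: TSV traces with a JSON metadata sidecar.

A recording is stored as tab-separated columns ``time_ms, V_mV, I_pA,
command`` plus ``<path>.json`` carrying the mode, sampling step and protocol
metadata.  The format is deliberately diffable and desk-scale; vendor binary
formats are an adapter concern, not a dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .protocols import Recording

__all__ = ["read_recording", "write_recording"]

COLUMNS = ("time_ms", "V_mV", "I_pA", "command")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as TSV plus a JSON sidecar; full float precision."""
    path = Path(path)
    df = pd.DataFrame({
        "time_ms": rec.t, "V_mV": rec.V, "I_pA": rec.I, "command": rec.command,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "mode": rec.mode,
        "sample_dt": rec.sample_dt,
        "metadata": _jsonable(rec.metadata),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording(path) -> Recording:
    """Read a TSV recording and its JSON sidecar back into a Recording."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording file: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_ms"].to_numpy(float)
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))
        if dt.min() <= 0 or len(bad):
            i = int(bad[0]) if len(bad) else int(np.argmin(dt))
            raise FormatError(
                f"{path}: non-uniform time grid at row {i + 2} "
                f"(interval {dt[i]:g} vs {dt[0]:g})")
    sidecar_path = Path(str(path) + ".json")
    mode, meta = "CC", {}
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        mode = sc.get("mode", "CC")
        meta = sc.get("metadata", {}) or {}
    return Recording(mode=mode, t=t, V=df["V_mV"].to_numpy(float),
                     I=df["I_pA"].to_numpy(float),
                     command=df["command"].to_numpy(float), metadata=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
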