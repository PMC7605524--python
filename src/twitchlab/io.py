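"""Trace file I/O: two-column CSV with '#' metadata comments."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .trace import TwitchTrace

__all__ = ["read_trace", "write_trace"]

#: relative jitter allowed on the time grid of a file before rejection
GRID_RTOL = 1e-6


def write_trace(trace: TwitchTrace, path: str | Path) -> None:
    """Write a trace as CSV (time_ms, tension) with a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# source: {trace.source}\n")
        if trace.SL is not None:
            fh.write(f"# SL_um: {trace.SL}\n")
        for key in ("dt", "param_hash", "seed"):
            if key in trace.meta:
                fh.write(f"# {key}: {trace.meta[key]}\n")
        fh.write("time_ms,tension\n")
        for t, T in zip(trace.t.tolist(), trace.T.tolist()):
            fh.write(f"{t!r},{T!r}\n")


def read_trace(path: str | Path) -> TwitchTrace:
    """Read a two-column trace CSV written by :func:`write_trace`.

    '#'-prefixed ``key: value`` comments populate units/source/SL
    metadata; unknown files default to ms and mN/mm^2.  The time grid
    must be uniform and strictly increasing.
    """
    path = Path(path)
    meta: dict = {}
    units, source, SL = "mN/mm^2", "experimental", None
    t_vals, T_vals = [], []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key == "units":
                        units = val
                    elif key == "source":
                        source = val
                    elif key == "SL_um":
                        SL = float(val)
                    else:
                        meta[key] = val
                continue
            if not header_seen and not line[0].isdigit() and line[0] != "-":
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, "
                                 f"got {len(parts)}")
            try:
                t_vals.append(float(parts[0]))
                T_vals.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    t = np.asarray(t_vals)
    T = np.asarray(T_vals)
    if t.size < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    if np.any(~np.isfinite(T)):
        bad = int(np.flatnonzero(~np.isfinite(T))[0])
        raise ValueError(f"{path}: non-finite tension at data row {bad}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if np.max(np.abs(dt - dt[0])) > GRID_RTOL * max(abs(dt[0]), 1.0):
        raise ValueError(f"{path}: non-uniform time grid")
    return TwitchTrace(t=t, T=T, units=units, source=source, SL=SL, meta=meta)
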