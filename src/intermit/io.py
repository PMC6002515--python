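"""Delimited-text I/O for series, events and traces.

All files are tab-separated with a header row; values round-trip at full
float precision. Series files must be uniformly sampled (checked to within
1 microsecond).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AdjustmentEvent, ControllerTrace
from .series import UniformSeries

__all__ = [
    "read_series",
    "write_series",
    "read_events",
    "write_events",
    "write_trace",
    "write_keyvalues",
    "read_keyvalues",
]

_TIME_TOL = 1e-6  # s


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")


def write_series(path, series: UniformSeries, name: str = "C") -> None:
    df = pd.DataFrame({"t": series.times, name: series.values})
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_series(path, name: str = "C") -> UniformSeries:
    """Read a uniformly sampled series; errors on non-uniform timestamps
    or a missing column."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["t", name], path)
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = (t[-1] - t[0]) / (len(t) - 1)
    if np.max(np.abs(t - (t[0] + dt * np.arange(len(t))))) > _TIME_TOL:
        raise ValueError(f"{path}: non-uniform sampling (tolerance {_TIME_TOL} s)")
    return UniformSeries(float(t[0]), float(dt), df[name].to_numpy(dtype=float))


def write_events(path, events: Sequence[AdjustmentEvent],
                 overfit_flags=None) -> None:
    df = pd.DataFrame({
        "t_i": [ev.t for ev in events],
        "eps_i": [ev.eps for ev in events],
        "m_i": [ev.m for ev in events],
        "amp": [ev.amplitude for ev in events],
    })
    if overfit_flags is not None:
        df["overfit_flag"] = np.asarray(overfit_flags).astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_events(path) -> list[AdjustmentEvent]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["t_i", "amp"], path)
    eps = df["eps_i"] if "eps_i" in df.columns else df["amp"]
    m = df["m_i"] if "m_i" in df.columns else 0.0 * df["amp"]
    return [AdjustmentEvent(t=float(t), eps=float(e), m=float(mm),
                            eps_tilde=float(e) * (1.0 + float(mm)),
                            amplitude=float(a), direction=int(np.sign(a)))
            for t, e, mm, a in zip(df["t_i"], eps, m, df["amp"])]


def write_trace(path, trace: ControllerTrace) -> None:
    """One row per sample: t, A, P, Pr, Pp, eps, C, Cdot."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def write_keyvalues(path, d: dict) -> None:
    with open(path, "w") as f:
        for k, v in d.items():
            f.write(f"{k}\t{v}\n")


def read_keyvalues(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, v = line.split("\t", 1)
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out
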