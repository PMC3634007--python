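"""Readers and writers for the package's plain-text formats.

Raw recordings travel as delimited text with a ``time,x,y,z`` header:
time either in seconds (numeric) or ISO-8601, acceleration in g.  All
tabular outputs are CSV.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RecordingParseError
from .evaluation import BandSummary, ConditionResult
from .recording import TriaxialRecording

__all__ = ["read_recording", "write_recording", "results_frame", "bands_frame"]

MAX_FS_JITTER = 0.01


def read_recording(path: str | os.PathLike) -> TriaxialRecording:
    """Parse a ``time,x,y,z`` delimited text file into a recording.

    The sampling frequency is inferred from the median time step; time
    must be strictly increasing with step jitter below 1%.  Errors name
    the offending line (header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise RecordingParseError(f"{path}: {exc}") from exc
    expected = ["time", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise RecordingParseError(
            f"{path}: header must be {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    if len(df) < 2:
        raise RecordingParseError(f"{path}: need at least two samples to infer fs")

    time_col = df["time"]
    if time_col.dtype == object:
        try:
            parsed = pd.to_datetime(time_col, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise RecordingParseError(f"{path}: unparseable time column: {exc}") from exc
        midnight = parsed.dt.normalize()
        seconds = (parsed - midnight).dt.total_seconds().to_numpy()
    else:
        seconds = time_col.to_numpy(dtype=float)

    for col in ("x", "y", "z"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            raise RecordingParseError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )

    dt = np.diff(seconds)
    nonpos = np.nonzero(dt <= 0)[0]
    if len(nonpos):
        raise RecordingParseError(
            f"{path}: time not strictly increasing at line {nonpos[0] + 3}"
        )
    median_dt = float(np.median(dt))
    if np.max(np.abs(dt - median_dt)) > MAX_FS_JITTER * median_dt:
        worst = int(np.argmax(np.abs(dt - median_dt)))
        raise RecordingParseError(
            f"{path}: sampling-interval jitter above {MAX_FS_JITTER:.0%} at line {worst + 3}"
        )
    fs = 1.0 / median_dt
    # snap away float noise from the reciprocal so downstream whole-sample
    # checks (e.g. samples per epoch) see the intended rate
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    data = df[["x", "y", "z"]].to_numpy(dtype=float)
    return TriaxialRecording(fs=fs, data=data, start_time=float(seconds[0]))


def write_recording(path: str | os.PathLike, rec: TriaxialRecording) -> None:
    """Write a recording as ``time,x,y,z`` CSV (time in seconds-of-day)."""
    times = rec.start_time + rec.t
    df = pd.DataFrame(
        {"time": times, "x": rec.x, "y": rec.y, "z": rec.z}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def results_frame(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """Condition-level bench results as a tidy DataFrame."""
    return pd.DataFrame([vars(r) for r in results])


def bands_frame(bands: Sequence[BandSummary]) -> pd.DataFrame:
    """Band summaries as a tidy DataFrame mirroring the summary table."""
    rows = []
    for b in bands:
        rows.append(
            {
                "freq_lo_hz": b.freq_band[0],
                "freq_hi_hz": b.freq_band[1],
                "angle_min_deg": b.angle_range[0],
                "angle_max_deg": b.angle_range[1],
                "radius_lo_m": b.radius_band[0],
                "radius_hi_m": b.radius_band[1],
                "metric": b.metric,
                "n": b.n,
                "mean_reference_mg": b.mean_reference_mg,
                "mean_error_mg": b.mean_error_mg,
                "mean_abs_error_mg": b.mean_abs_error_mg,
                "mean_rel_error_pct": b.mean_rel_error_pct,
            }
        )
    return pd.DataFrame(rows)
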