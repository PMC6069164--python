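"""Readers and writers for the on-disk skeleton and accelerometer formats.

Skeleton CSV layout (one row per frame, UTF-8, '.' decimal separator):

    frame, t, floor_A, floor_B, floor_C, floor_D,
    <joint>_x, <joint>_y, <joint>_z, <joint>_state   (for each of the 20 joints)

A JSON-lines twin with the same field names per record is also supported.
Coordinates are meters in x-right / y-up / z-depth sensor space; a header
comment line declares this in CSV files.

The accelerometer reader and the height-from-acceleration adapter emulate
benchmark exports that provide only an acceleration magnitude trace plus
an initial height; the reconstruction is a documented heuristic for
driving the detector, not a physical model.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    JOINT_NAMES,
    AccelerationSeries,
    FloorPlane,
    FormatError,
    JointPosition,
    SkeletonFrame,
    SkeletonStream,
    TrackingState,
    ValidationError,
)

__all__ = [
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_skeleton_jsonl",
    "write_skeleton_jsonl",
    "read_accelerometer_csv",
    "height_series_from_acceleration",
]

_COORD_HEADER = "# fallsense skeleton stream: meters, x-right / y-up / z-depth"
_PRECISION = 6
_GRAVITY = 9.81

_MANDATORY = ["frame", "t", "floor_A", "floor_B", "floor_C", "floor_D"]


def _frame_from_row(row: pd.Series) -> SkeletonFrame:
    joints: dict[str, JointPosition] = {}
    for name in JOINT_NAMES:
        try:
            x = float(row[f"{name}_x"])
            y = float(row[f"{name}_y"])
            z = float(row[f"{name}_z"])
            state = TrackingState(str(row[f"{name}_state"]))
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError
        except (ValueError, TypeError, KeyError):
            joints[name] = JointPosition.untracked()
            continue
        joints[name] = JointPosition(x, y, z, state)
    floor = FloorPlane(
        float(row["floor_A"]), float(row["floor_B"]),
        float(row["floor_C"]), float(row["floor_D"]),
    )
    return SkeletonFrame(
        frame_index=int(row["frame"]), timestamp=float(row["t"]),
        joints=joints, floor=floor,
    )


def _stream_from_df(df: pd.DataFrame, source: str) -> SkeletonStream:
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    frames = [_frame_from_row(row) for _, row in df.iterrows()]
    try:
        return SkeletonStream(frames, metadata={"source": source})
    except ValidationError as exc:
        raise ValidationError(f"{source}: {exc}") from exc


def read_skeleton_csv(path: str | Path) -> SkeletonStream:
    """Read a skeleton stream from the documented CSV layout.

    Rows with unparseable joint cells keep the frame but mark those
    joints ``not_tracked``.  Non-monotone timestamps raise
    :class:`ValidationError`; missing mandatory columns raise
    :class:`FormatError` naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    return _stream_from_df(df, str(path))


def _stream_to_df(stream: SkeletonStream) -> pd.DataFrame:
    rows = []
    for fr in stream:
        row: dict = {
            "frame": fr.frame_index,
            "t": round(fr.timestamp, _PRECISION),
            "floor_A": fr.floor.A, "floor_B": fr.floor.B,
            "floor_C": fr.floor.C, "floor_D": fr.floor.D,
        }
        for name in JOINT_NAMES:
            j = fr.joint(name)
            if j.usable:
                row[f"{name}_x"] = round(j.x, _PRECISION)
                row[f"{name}_y"] = round(j.y, _PRECISION)
                row[f"{name}_z"] = round(j.z, _PRECISION)
            else:
                row[f"{name}_x"] = row[f"{name}_y"] = row[f"{name}_z"] = ""
            row[f"{name}_state"] = j.tracking_state.value
        rows.append(row)
    return pd.DataFrame(rows)


def write_skeleton_csv(stream: SkeletonStream, path: str | Path) -> Path:
    """Write a stream; round-trips through :func:`read_skeleton_csv` to
    6 decimal places.  Empty streams are an error."""
    if len(stream) == 0:
        raise ValidationError("cannot write an empty stream")
    path = Path(path)
    df = _stream_to_df(stream)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_COORD_HEADER + "\n")
        df.to_csv(fh, index=False)
    return path


def write_skeleton_jsonl(stream: SkeletonStream, path: str | Path) -> Path:
    if len(stream) == 0:
        raise ValidationError("cannot write an empty stream")
    path = Path(path)
    df = _stream_to_df(stream)
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in df.iterrows():
            rec = {k: (None if v == "" else v) for k, v in row.items()}
            fh.write(json.dumps(rec) + "\n")
    return path


def read_skeleton_jsonl(path: str | Path) -> SkeletonStream:
    path = Path(path)
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    if not records:
        raise FormatError(f"{path}: empty JSON-lines file")
    df = pd.DataFrame(records)
    return _stream_from_df(df, str(path))


def read_accelerometer_csv(path: str | Path, unit: str = "m/s2") -> AccelerationSeries:
    """Read a two-column (t, a_mag) CSV into SI units.

    ``unit`` must be ``"m/s2"`` or ``"g"`` (values multiplied by 9.81);
    benchmark exports do not declare their units, so the caller must.
    Non-numeric cells raise :class:`FormatError` with the row number.
    """
    if unit not in ("m/s2", "g"):
        raise ValueError(f"unknown accelerometer unit {unit!r}")
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns (t, a_mag)")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    t_col, a_col = df.columns[0], df.columns[1]
    if "t" in df.columns:
        t_col = "t"
    if "a_mag" in df.columns:
        a_col = "a_mag"
    ts, mags = [], []
    scale = _GRAVITY if unit == "g" else 1.0
    for i, row in df.iterrows():
        try:
            ts.append(float(row[t_col]))
            mags.append(float(row[a_col]) * scale)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell at data row {i}") from exc
        if not (math.isfinite(ts[-1]) and math.isfinite(mags[-1])):
            raise FormatError(f"{path}: non-numeric cell at data row {i}")
    return AccelerationSeries(ts, mags)


def height_series_from_acceleration(
    initial_height: float,
    series: AccelerationSeries,
    mode: str = "variation",
    scale: float = 1.0,
    gravity: float = _GRAVITY,
) -> np.ndarray:
    """Reconstruct a head-height trace from an acceleration-magnitude trace.

    The reconstruction starts at ``initial_height`` (taken from a depth
    frame) and subtracts the variation of the acceleration signal around
    gravity.  Two selectable heuristics:

    ``"variation"`` (default)
        cumulative subtraction of ``|a - g| * dt * scale`` — the height
        only ever decreases while the signal deviates from rest.
    ``"double_integration"``
        treats ``a - g`` as a vertical acceleration and integrates it
        twice into a downward displacement.

    Heights are clipped at 0; a joint cannot go below the floor.
    """
    if initial_height <= 0:
        raise ValueError("initial_height must be positive")
    if len(series) < 2:
        raise ValueError("need at least 2 acceleration samples")
    if mode not in ("variation", "double_integration"):
        raise ValueError(f"unknown reconstruction mode {mode!r}")
    t = np.asarray(series.timestamps, dtype=float)
    a = np.asarray(series.magnitude, dtype=float)
    dt = np.diff(t)
    h = np.empty(len(a), dtype=float)
    h[0] = initial_height
    if mode == "variation":
        drops = np.abs(a[1:] - gravity) * dt * scale
        h[1:] = initial_height - np.cumsum(drops)
    else:
        v = np.cumsum((a[1:] - gravity) * dt)  # downward speed, m/s
        h[1:] = initial_height - np.cumsum(v * dt) * scale
    return np.clip(h, 0.0, None)
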