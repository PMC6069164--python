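"""Per-frame kinematic quantities derived from a skeleton stream.

Quantities per frame: height of each key joint above the floor plane
(point-to-plane distance), movement direction of a tracking joint,
displacement (axis-aligned or irregular in-plane), speed and
acceleration.  Positions are compared two frames apart by default
(skip-one sampling), giving a 1/15 s interval at 30 frames/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .config import KinematicsConfig
from .types import (
    KEY_JOINTS,
    FloorPlane,
    JointPosition,
    SkeletonFrame,
    SkeletonStream,
    UnavailableValue,
)

__all__ = [
    "Direction",
    "KinematicSample",
    "joint_height",
    "movement_direction",
    "irregular_distance",
    "instantaneous_speed",
    "kinematic_sample",
    "compute_kinematics",
    "StreamKinematics",
]


class Direction(str, Enum):
    AXIS_X = "axis_x"
    AXIS_Y = "axis_y"
    AXIS_Z = "axis_z"
    IRREGULAR = "irregular"
    STATIONARY = "stationary"


@dataclass(frozen=True)
class KinematicSample:
    frame_index: int
    timestamp: float
    heights: dict            # joint name -> meters (None if untracked)
    displacement: float      # meters, tracking joint
    direction: Direction
    speed: float             # m/s, tracking-joint displacement / dt
    height_speeds: dict      # joint name -> |dH|/dt, m/s
    acceleration: float | None  # m/s^2, change of speed per sample interval


def joint_height(joint: JointPosition, plane: FloorPlane) -> float:
    """Point-to-plane distance |Ax + By + Cz + D| / sqrt(A^2+B^2+C^2).

    Invariant to rescaling the plane vector by any positive constant.
    Raises :class:`UnavailableValue` for untracked joints.
    """
    if not joint.usable:
        raise UnavailableValue("joint is not tracked")
    num = abs(plane.A * joint.x + plane.B * joint.y + plane.C * joint.z + plane.D)
    return num / plane.normal_length


def movement_direction(
    prev: JointPosition,
    curr: JointPosition,
    epsilon: float = 0.01,
    dominance_ratio: float = 0.8,
) -> Direction:
    """Classify the displacement between two positions.

    Stationary below ``epsilon`` total displacement; an axis direction
    when that axis carries at least ``dominance_ratio`` of the Euclidean
    displacement (ties go to the axis); irregular otherwise.
    """
    if not (prev.usable and curr.usable):
        raise UnavailableValue("both joints must be tracked")
    d = (curr.x - prev.x, curr.y - prev.y, curr.z - prev.z)
    total = math.sqrt(sum(v * v for v in d))
    if total < epsilon:
        return Direction.STATIONARY
    axes = (Direction.AXIS_X, Direction.AXIS_Y, Direction.AXIS_Z)
    k = max(range(3), key=lambda i: abs(d[i]))
    if abs(d[k]) >= dominance_ratio * total:
        return axes[k]
    return Direction.IRREGULAR


def irregular_distance(
    prev: JointPosition, curr: JointPosition, include_z: bool = False
) -> float:
    """Euclidean in-plane displacement sqrt((x-x')^2 + (y-y')^2).

    The depth axis is excluded by default; ``include_z`` generalizes to
    the full 3-D Euclidean distance.
    """
    if not (prev.usable and curr.usable):
        raise UnavailableValue("both joints must be tracked")
    dx, dy, dz = curr.x - prev.x, curr.y - prev.y, curr.z - prev.z
    if include_z:
        return math.sqrt(dx * dx + dy * dy + dz * dz)
    return math.hypot(dx, dy)


def instantaneous_speed(d_c: float, d_p: float, t_c: float, t_p: float) -> float:
    """|d_c - d_p| / (t_c - t_p); with skip-one sampling at 30 fps the
    denominator is 1/15 s."""
    if t_c <= t_p:
        raise ValueError("t_c must be greater than t_p")
    return abs(d_c - d_p) / (t_c - t_p)


def _axis_displacement(prev: JointPosition, curr: JointPosition, direction: Direction) -> float:
    axis = {"axis_x": 0, "axis_y": 1, "axis_z": 2}[direction.value]
    dp = (prev.x, prev.y, prev.z)
    dc = (curr.x, curr.y, curr.z)
    return abs(dc[axis] - dp[axis])


def kinematic_sample(
    frames: Sequence[SkeletonFrame],
    joint_set: Sequence[str] = KEY_JOINTS,
    config: KinematicsConfig | None = None,
    prev_sample: KinematicSample | None = None,
) -> KinematicSample:
    """Derive one sample from a short buffer of frames.

    The last frame is the current frame; the comparison frame is
    ``config.frame_skip + 1`` frames earlier (or the oldest available).
    Raises :class:`UnavailableValue` if fewer than 2 usable frames are
    supplied or the tracking joint is untracked in either frame.
    """
    cfg = config or KinematicsConfig()
    if len(frames) < 2:
        raise UnavailableValue("need at least 2 frames")
    curr = frames[-1]
    back = min(cfg.frame_skip + 1, len(frames) - 1)
    prev = frames[-1 - back]

    heights: dict[str, float | None] = {}
    for name in joint_set:
        j = curr.joint(name)
        heights[name] = joint_height(j, curr.floor) if j.usable else None

    tj_prev, tj_curr = prev.joint(cfg.tracking_joint), curr.joint(cfg.tracking_joint)
    if not (tj_prev.usable and tj_curr.usable):
        raise UnavailableValue(f"tracking joint {cfg.tracking_joint} untracked")
    dt = curr.timestamp - prev.timestamp
    direction = movement_direction(
        tj_prev, tj_curr, cfg.stationary_epsilon, cfg.dominance_ratio
    )
    if direction is Direction.STATIONARY:
        displacement = 0.0
    elif direction is Direction.IRREGULAR:
        displacement = irregular_distance(tj_prev, tj_curr, cfg.include_z_in_irregular)
    else:
        displacement = _axis_displacement(tj_prev, tj_curr, direction)
    speed = displacement / dt

    height_speeds: dict[str, float] = {}
    for name in joint_set:
        jp, jc = prev.joint(name), curr.joint(name)
        if jp.usable and jc.usable:
            height_speeds[name] = instantaneous_speed(
                joint_height(jc, curr.floor), joint_height(jp, prev.floor),
                curr.timestamp, prev.timestamp,
            )

    acceleration = None
    if prev_sample is not None:
        dts = curr.timestamp - prev_sample.timestamp
        if dts > 0:
            acceleration = (speed - prev_sample.speed) / dts
    return KinematicSample(
        frame_index=curr.frame_index,
        timestamp=curr.timestamp,
        heights=heights,
        displacement=displacement,
        direction=direction,
        speed=speed,
        height_speeds=height_speeds,
        acceleration=acceleration,
    )


@dataclass
class StreamKinematics:
    """Vectorized per-frame kinematics for a whole stream.

    Arrays are aligned with the stream's frames; entries that cannot be
    computed (leading frames, untracked joints) are NaN.  ``speed`` is
    the elementwise maximum of the tracking-joint displacement speed and
    the key-joint height speeds — the per-frame velocity magnitude the
    detector branches on.
    """

    timestamps: np.ndarray
    heights: dict           # joint -> np.ndarray (NaN when untracked)
    smooth_heights: dict    # joint -> rolling-median filtered heights
    direction: list         # per-frame Direction (or None)
    displacement_speed: np.ndarray
    height_speeds: dict     # joint -> np.ndarray
    speed: np.ndarray
    fine_speed: np.ndarray  # adjacent-frame head-channel speed (Process 3)
    acceleration: np.ndarray
    subject: np.ndarray     # bool, key joints tracked


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    s = pd.Series(x).rolling(window, min_periods=1, center=True).median()
    return s.to_numpy()


def compute_kinematics(
    stream: SkeletonStream,
    config: KinematicsConfig | None = None,
    joint_set: Sequence[str] = KEY_JOINTS,
) -> StreamKinematics:
    """Compute the detector's per-frame quantities for a whole stream."""
    cfg = config or KinematicsConfig()
    n = len(stream)
    t = np.array([f.timestamp for f in stream], dtype=float)

    heights: dict[str, np.ndarray] = {}
    coords: dict[str, np.ndarray] = {}
    for name in set(joint_set) | {cfg.tracking_joint}:
        h = np.full(n, np.nan)
        c = np.full((n, 3), np.nan)
        for i, fr in enumerate(stream):
            j = fr.joint(name)
            if j.usable:
                h[i] = joint_height(j, fr.floor)
                c[i] = (j.x, j.y, j.z)
        heights[name] = h
        coords[name] = c

    smooth_heights = {k: _rolling_median(v, 5) for k, v in heights.items()}
    subject = np.array([f.tracked(*KEY_JOINTS) for f in stream])

    back = cfg.frame_skip + 1
    direction: list = [None] * n
    disp_speed = np.full(n, np.nan)
    tc = coords[cfg.tracking_joint]
    for i in range(back, n):
        d = tc[i] - tc[i - back]
        if np.any(np.isnan(d)):
            continue
        dt = t[i] - t[i - back]
        total = float(np.linalg.norm(d))
        if total < cfg.stationary_epsilon:
            direction[i] = Direction.STATIONARY
            disp_speed[i] = 0.0
            continue
        k = int(np.argmax(np.abs(d)))
        if abs(d[k]) >= cfg.dominance_ratio * total:
            direction[i] = (Direction.AXIS_X, Direction.AXIS_Y, Direction.AXIS_Z)[k]
            disp = abs(d[k])
        else:
            direction[i] = Direction.IRREGULAR
            disp = (
                float(np.linalg.norm(d)) if cfg.include_z_in_irregular
                else float(np.hypot(d[0], d[1]))
            )
        disp_speed[i] = disp / dt

    height_speeds: dict[str, np.ndarray] = {}
    for name in joint_set:
        hs = np.full(n, np.nan)
        h = heights[name]
        hs[back:] = np.abs(h[back:] - h[:-back]) / (t[back:] - t[:-back])
        height_speeds[name] = hs

    stacked = np.vstack([disp_speed] + [height_speeds[j] for j in joint_set])
    filled = np.where(np.isnan(stacked), -np.inf, stacked)
    speed = filled.max(axis=0)
    speed[~np.isfinite(speed)] = np.nan

    fine = np.full(n, np.nan)
    h_head = heights.get("head", np.full(n, np.nan))
    fine[1:] = np.abs(h_head[1:] - h_head[:-1]) / (t[1:] - t[:-1])

    smooth_speed = _rolling_median(speed, cfg.speed_median_window)
    accel = np.full(n, np.nan)
    accel[1:] = (smooth_speed[1:] - smooth_speed[:-1]) / (t[1:] - t[:-1])

    return StreamKinematics(
        timestamps=t,
        heights=heights,
        smooth_heights=smooth_heights,
        direction=direction,
        displacement_speed=disp_speed,
        height_speeds=height_speeds,
        speed=speed,
        fine_speed=fine,
        acceleration=accel,
        subject=subject,
    )
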