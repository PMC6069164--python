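"""Gait-derived fall-risk factors and the low/high risk flag.

Three factors are measured on pairs of frames (a previous frame PF and a
current frame CF):

step symmetry
    the change in the left/right foot separation along the movement
    axis.  By default the pipeline differences the separation
    *magnitudes* with PF and CF one step apart, so the value is the
    difference between the left and the right step length — the step
    inequality the factor is meant to capture.  The signed variant
    (plain difference of ``R - L``) is available via ``rectify=False``.
trunk sway
    the lateral offset of the torso from the hip midpoint, averaged
    over the two frames; a proxy for side-to-side lean.
arm spread
    the change in the mean lateral torso-to-arm distance between the
    frames; arms opening suggests a balance-recovery attempt.

The lateral axis is x when the subject moves along z and vice versa;
step symmetry uses the movement axis itself.  A window of factor
samples is aggregated (mean of absolute values by default) and the risk
level is HIGH as soon as any aggregate exceeds its threshold — any
gait abnormality triggers intensive monitoring.

The PF/CF lag is one step period, estimated per window from the
autocorrelation of the foot-separation signal; where no gait period is
detectable (standing, sitting) a configured fallback lag is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import RiskConfig
from .types import SkeletonFrame, SkeletonStream, UnavailableValue

__all__ = [
    "RiskLevel",
    "RiskFactorSample",
    "RiskAssessment",
    "InsufficientDataError",
    "step_symmetry",
    "trunk_sway",
    "spread_arm",
    "assess_risk",
    "assess_stream",
    "compute_factor_series",
    "estimate_step_lag",
    "rolling_risk",
]

log = logging.getLogger(__name__)

_FACTORS = ("step_symmetry", "trunk_sway", "spread_arm")


class RiskLevel(str, Enum):
    LOW = "low"
    HIGH = "high"


class InsufficientDataError(Exception):
    """The factor window is too short for an assessment."""


@dataclass(frozen=True)
class RiskFactorSample:
    frame_index: int
    step_symmetry: float
    trunk_sway: float
    spread_arm: float


@dataclass(frozen=True)
class RiskAssessment:
    level: RiskLevel
    window: tuple[int, int]   # first/last frame_index of the window
    evidence: dict            # per-factor aggregates and thresholds


def _coord(frame: SkeletonFrame, joint: str, axis: str) -> float:
    j = frame.joint(joint)
    if not j.usable:
        raise UnavailableValue(f"joint {joint} untracked")
    return getattr(j, axis)


def _movement_axis(pf: SkeletonFrame, cf: SkeletonFrame, direction) -> str:
    value = getattr(direction, "value", direction)
    if value == "axis_x":
        return "x"
    if value == "axis_z":
        return "z"
    # irregular / vertical movement: fall back to the dominant horizontal axis
    try:
        dx = abs(_coord(cf, "shoulder_center", "x") - _coord(pf, "shoulder_center", "x"))
        dz = abs(_coord(cf, "shoulder_center", "z") - _coord(pf, "shoulder_center", "z"))
    except UnavailableValue:
        dx, dz = 1.0, 0.0
    axis = "x" if dx >= dz else "z"
    log.debug("direction %s not axis-aligned; using dominant axis %s", value, axis)
    return axis


def step_symmetry(
    pf: SkeletonFrame,
    cf: SkeletonFrame,
    direction,
    rectify: bool = True,
) -> float:
    """Difference of the foot separations between PF and CF along the
    movement axis; with ``rectify`` the separation magnitudes are
    differenced (step inequality)."""
    axis = _movement_axis(pf, cf, direction)
    sep_pf = _coord(pf, "foot_r", axis) - _coord(pf, "foot_l", axis)
    sep_cf = _coord(cf, "foot_r", axis) - _coord(cf, "foot_l", axis)
    if rectify:
        return abs(sep_pf) - abs(sep_cf)
    return sep_pf - sep_cf


def _lateral_axis(pf, cf, direction) -> str:
    return "z" if _movement_axis(pf, cf, direction) == "x" else "x"


def trunk_sway(
    pf: SkeletonFrame,
    cf: SkeletonFrame,
    direction,
    aliases: dict | None = None,
) -> float:
    """Average lateral torso offset from the hip midpoint over PF and CF."""
    torso = (aliases or {}).get("torso", "torso")
    axis = _lateral_axis(pf, cf, direction)

    def offset(fr: SkeletonFrame) -> float:
        mid = 0.5 * (_coord(fr, "hip_l", axis) + _coord(fr, "hip_r", axis))
        return _coord(fr, torso, axis) - mid

    return 0.5 * (offset(pf) + offset(cf))


def spread_arm(
    pf: SkeletonFrame,
    cf: SkeletonFrame,
    direction,
    aliases: dict | None = None,
) -> float:
    """Change of the mean lateral torso-to-arm distance from PF to CF;
    positive when the arms are opening."""
    al = aliases or {}
    torso = al.get("torso", "torso")
    arm_l, arm_r = al.get("arm_l", "hand_l"), al.get("arm_r", "hand_r")
    axis = _lateral_axis(pf, cf, direction)

    def mean_dist(fr: SkeletonFrame) -> float:
        tx = _coord(fr, torso, axis)
        return 0.5 * (
            abs(tx - _coord(fr, arm_r, axis)) + abs(tx - _coord(fr, arm_l, axis))
        )

    return mean_dist(cf) - mean_dist(pf)


# ---------------------------------------------------------------------------
# windowed pipeline


def _series(stream: SkeletonStream, joint: str, axis: str, smooth: int) -> np.ndarray:
    idx = {"x": 0, "y": 1, "z": 2}[axis]
    out = np.full(len(stream), np.nan)
    for i, fr in enumerate(stream):
        j = fr.joint(joint)
        if j.usable:
            out[i] = (j.x, j.y, j.z)[idx]
    if smooth > 1:
        out = pd.Series(out).rolling(smooth, min_periods=1, center=True).median().to_numpy()
    return out


def estimate_step_lag(sep: np.ndarray, fps: float, config: RiskConfig) -> int | None:
    """Estimate the step period (frames) from the foot-separation signal.

    Returns half the lag of the strongest autocorrelation peak inside the
    stride-period search range, or None when the signal is aperiodic.
    """
    x = sep[np.isfinite(sep)]
    lo = max(2, int(round(config.stride_search[0] * fps)))
    hi = int(round(config.stride_search[1] * fps))
    if len(x) < lo + int(0.5 * fps) or hi <= lo:
        return None
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var < 1e-9:
        return None
    hi = min(hi, len(x) - 2)
    if hi <= lo:
        return None
    ac = np.array([np.dot(x[:-k], x[k:]) / var for k in range(lo, hi + 1)])
    best = int(np.argmax(ac))
    if ac[best] < config.stride_min_corr:
        return None
    stride = lo + best
    return max(1, stride // 2)


def _dominant_axis(sc_x: np.ndarray, sc_z: np.ndarray) -> str:
    def span(a: np.ndarray) -> float:
        f = a[np.isfinite(a)]
        return abs(f[-1] - f[0]) if len(f) >= 2 else 0.0

    return "x" if span(sc_x) >= span(sc_z) else "z"


def _factor_arrays(
    stream: SkeletonStream, config: RiskConfig, lag: int, move_axis: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lat_axis = "z" if move_axis == "x" else "x"
    sm = config.smooth_window
    al = config.joint_aliases
    fr_ = _series(stream, "foot_r", move_axis, sm)
    fl_ = _series(stream, "foot_l", move_axis, sm)
    sep = fr_ - fl_
    torso = _series(stream, al.get("torso", "torso"), lat_axis, sm)
    hip_mid = 0.5 * (
        _series(stream, "hip_l", lat_axis, sm) + _series(stream, "hip_r", lat_axis, sm)
    )
    arm_r = _series(stream, al.get("arm_r", "hand_r"), lat_axis, sm)
    arm_l = _series(stream, al.get("arm_l", "hand_l"), lat_axis, sm)
    mean_dist = 0.5 * (np.abs(torso - arm_r) + np.abs(torso - arm_l))
    offset = torso - hip_mid

    n = len(stream)
    ss = np.full(n, np.nan)
    tw = np.full(n, np.nan)
    sa = np.full(n, np.nan)
    if n > lag:
        if config.rectify_step:
            ss[lag:] = np.abs(sep[:-lag]) - np.abs(sep[lag:])
        else:
            ss[lag:] = sep[:-lag] - sep[lag:]
        tw[lag:] = 0.5 * (offset[:-lag] + offset[lag:])
        sa[lag:] = mean_dist[lag:] - mean_dist[:-lag]
    return ss, tw, sa


def compute_factor_series(
    stream: SkeletonStream, config: RiskConfig | None = None
) -> list[RiskFactorSample]:
    """Per-frame factor samples for a whole stream, using one step-period
    estimate for the PF/CF lag."""
    cfg = config or RiskConfig()
    sm = cfg.smooth_window
    sc_x = _series(stream, "shoulder_center", "x", sm)
    sc_z = _series(stream, "shoulder_center", "z", sm)
    move_axis = _dominant_axis(sc_x, sc_z)
    sep = _series(stream, "foot_r", move_axis, sm) - _series(stream, "foot_l", move_axis, sm)
    lag = None
    if cfg.auto_stride:
        lag = estimate_step_lag(sep, stream.fps, cfg)
    if lag is None:
        lag = cfg.pair_lag_frames
    ss, tw, sa = _factor_arrays(stream, cfg, lag, move_axis)
    frames = stream.frames
    return [
        RiskFactorSample(frames[i].frame_index, ss[i], tw[i], sa[i])
        for i in range(len(frames))
    ]


def assess_risk(
    window: list[RiskFactorSample], config: RiskConfig | None = None
) -> RiskAssessment:
    """Aggregate a window of factor samples into a low/high risk flag.

    HIGH iff any factor aggregate exceeds its threshold (OR rule).
    Raises :class:`InsufficientDataError` when fewer than
    ``config.window_frames`` finite samples are available.
    """
    cfg = config or RiskConfig()
    vals = {f: np.array([getattr(s, f) for s in window], dtype=float) for f in _FACTORS}
    finite = {f: v[np.isfinite(v)] for f, v in vals.items()}
    n_usable = max((len(v) for v in finite.values()), default=0)
    if n_usable < cfg.window_frames:
        raise InsufficientDataError(
            f"{n_usable} usable factor samples < window_frames={cfg.window_frames}"
        )
    agg_fn = np.max if cfg.aggregate == "max_abs" else np.mean
    thresholds = {
        "step_symmetry": cfg.threshold_step_symmetry,
        "trunk_sway": cfg.threshold_trunk_sway,
        "spread_arm": cfg.threshold_spread_arm,
    }
    aggregates = {
        f: (float(agg_fn(np.abs(v))) if len(v) else math.nan)
        for f, v in finite.items()
    }
    crossed = [
        f for f in _FACTORS
        if np.isfinite(aggregates[f]) and aggregates[f] > thresholds[f]
    ]
    level = RiskLevel.HIGH if crossed else RiskLevel.LOW
    return RiskAssessment(
        level=level,
        window=(window[0].frame_index, window[-1].frame_index),
        evidence={
            "aggregates": aggregates,
            "thresholds": thresholds,
            "crossed": crossed,
            "aggregate_rule": cfg.aggregate,
            "n_samples": n_usable,
        },
    )


def assess_stream(
    stream: SkeletonStream, config: RiskConfig | None = None
) -> RiskAssessment:
    """Assess risk over all factor samples of a stream."""
    cfg = config or RiskConfig()
    return assess_risk(compute_factor_series(stream, cfg), cfg)


def rolling_risk(
    stream: SkeletonStream,
    config: RiskConfig | None = None,
    refresh: int = 15,
) -> np.ndarray:
    """Causal per-frame HIGH-risk flags over a stream.

    The step-period estimate is refreshed every ``refresh`` frames from
    the trailing signal; each frame's flag aggregates the trailing
    ``window_frames`` factor samples.  Frames without a full window are
    LOW (logged fallback).
    """
    cfg = config or RiskConfig()
    n = len(stream)
    fps = stream.fps
    sm = cfg.smooth_window
    sc_x = _series(stream, "shoulder_center", "x", sm)
    sc_z = _series(stream, "shoulder_center", "z", sm)
    est_win = max(cfg.window_frames, int(round(3.0 * fps)))

    ss = np.full(n, np.nan)
    tw = np.full(n, np.nan)
    sa = np.full(n, np.nan)
    for i0 in range(0, n, refresh):
        i1 = min(i0 + refresh, n)
        j0 = max(0, i0 - est_win)
        move_axis = _dominant_axis(sc_x[j0:i1], sc_z[j0:i1])
        sep_hist = (
            _series(stream, "foot_r", move_axis, sm)[j0:i0]
            - _series(stream, "foot_l", move_axis, sm)[j0:i0]
        )
        lag = estimate_step_lag(sep_hist, fps, cfg) if cfg.auto_stride else None
        if lag is None:
            lag = cfg.pair_lag_frames
        bss, btw, bsa = _factor_arrays(stream, cfg, lag, move_axis)
        ss[i0:i1], tw[i0:i1], sa[i0:i1] = bss[i0:i1], btw[i0:i1], bsa[i0:i1]

    win = cfg.window_frames
    high = np.zeros(n, dtype=bool)
    for arr, thr in (
        (ss, cfg.threshold_step_symmetry),
        (tw, cfg.threshold_trunk_sway),
        (sa, cfg.threshold_spread_arm),
    ):
        s = pd.Series(np.abs(arr))
        if cfg.aggregate == "max_abs":
            agg = s.rolling(win, min_periods=win).max()
        else:
            agg = s.rolling(win, min_periods=win).mean()
        high |= (agg > thr).fillna(False).to_numpy()
    return high
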