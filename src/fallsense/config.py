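"""Configuration for the whole pipeline.

All tunable thresholds live here, grouped by stage, and can be loaded
from a YAML file with the ``kinematics.*`` / ``risk.*`` / ``detector.*``
namespaces.  Units are meters, seconds, m/s and m/s^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .types import DEFAULT_JOINT_ALIASES

__all__ = ["KinematicsConfig", "RiskConfig", "DetectorConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class KinematicsConfig:
    #: frames skipped between the two compared frames; 1 gives the 1/15 s
    #: interval at 30 fps.
    frame_skip: int = 1
    #: displacement (m) per sample below which motion counts as stationary
    stationary_epsilon: float = 0.01
    #: fraction of the Euclidean displacement one axis must carry to be
    #: classified as axis-aligned motion (ties go to the axis)
    dominance_ratio: float = 0.8
    #: include the depth axis in the irregular-movement distance (the
    #: printed formula is 2-D; off by default)
    include_z_in_irregular: bool = False
    #: window of the moving-median smoothing applied to speed before
    #: differencing it into acceleration
    speed_median_window: int = 3
    #: tracking joint whose displacement defines direction and speed
    tracking_joint: str = "shoulder_center"


@dataclass(frozen=True)
class RiskConfig:
    #: minimum number of factor samples aggregated into one assessment
    window_frames: int = 60
    #: fallback PF/CF lag (frames) when no gait period can be estimated
    pair_lag_frames: int = 10
    #: estimate the per-window step period from the foot-separation
    #: autocorrelation and pair frames one step apart
    auto_stride: bool = True
    #: stride-period search range (seconds) for the autocorrelation
    stride_search: tuple[float, float] = (0.8, 2.5)
    #: minimum normalized autocorrelation to accept a period estimate
    stride_min_corr: float = 0.2
    threshold_step_symmetry: float = 0.10
    threshold_trunk_sway: float = 0.05
    threshold_spread_arm: float = 0.15
    #: 'mean_abs' or 'max_abs'
    aggregate: str = "mean_abs"
    #: difference the foot-separation magnitudes (= step lengths when the
    #: two frames are a step apart); False gives the signed difference
    rectify_step: bool = True
    #: rolling-median window applied to the coordinate series feeding the
    #: gait factors
    smooth_window: int = 5
    joint_aliases: dict = field(default_factory=lambda: dict(DEFAULT_JOINT_ALIASES))


@dataclass(frozen=True)
class DetectorConfig:
    velocity_high: float = 2.0          # m/s, potential-fall speed threshold
    near_floor_height: float = 0.5      # m, head near-floor threshold
    confirm_window: float = 1.5         # s, stage-2 observation window
    recovery_height: float = 0.8        # m, rising above this cancels a fall
    acceleration_high: float = 10.0     # m/s^2
    buffer_seconds: float = 3.0         # shared ring-buffer span
    #: sensitive-path multipliers (Process 3)
    risk_velocity_factor: float = 0.75
    risk_floor_factor: float = 1.25
    #: deliberate-descent recognizer
    slow_descent_seconds: float = 2.0   # s, minimum duration of a deliberate descent
    slow_descent_max_speed: float = 1.0  # m/s, peak head speed of a deliberate descent
    #: walking/running height fluctuations smaller than this never confirm
    fluctuation_amp: float = 0.15       # m
    #: lookback before a candidate when measuring the net drop
    descent_lookback: float = 2.0       # s
    #: baseline (frames) over which descent slopes are measured; 1/3 s at
    #: 30 fps — short enough to resolve a collapse, long enough to
    #: average out joint jitter
    descent_window_frames: int = 10
    #: windowed head speed (m/s) above which a frame counts as descending
    #: (or, with opposite sign, as rising and ending a descent run)
    descent_speed_threshold: float = 0.06
    #: consecutive neither-descending-nor-rising frames tolerated inside
    #: a descent run
    descent_grace: int = 8

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"detector config {f.name} must be positive")
        if self.near_floor_height >= self.recovery_height:
            raise ValueError("near_floor_height must be below recovery_height")


@dataclass(frozen=True)
class PipelineConfig:
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)


def _build(cls: type, data: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is RiskConfig and "stride_search" in data:
        data = {**data, "stride_search": tuple(data["stride_search"])}
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file with top-level keys
    ``kinematics``, ``risk`` and ``detector`` (all optional)."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for ns, kv in overrides.items():
            data.setdefault(ns, {}).update(kv)
    return PipelineConfig(
        kinematics=_build(KinematicsConfig, data.get("kinematics", {})),
        risk=_build(RiskConfig, data.get("risk", {})),
        detector=_build(DetectorConfig, data.get("detector", {})),
    )


def with_detector(config: PipelineConfig, **kwargs) -> PipelineConfig:
    """Convenience: a copy of ``config`` with detector fields replaced."""
    return replace(config, detector=replace(config.detector, **kwargs))
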