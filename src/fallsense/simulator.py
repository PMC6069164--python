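"""Seeded generator of labelled synthetic skeleton streams.

The generator emulates a Kinect-v1-style front-view recording of one
subject: 20 named joints in metric sensor space (x-right / y-up /
z-depth), a constant floor-clipping vector at the camera height, and
30 frames/s.  Motion is stylized — piecewise-smooth posture blends plus
per-joint Gaussian jitter — not biomechanical: the detector only needs
the rapid changes and the drop of the key joints, not accurate limb
trajectories.

Activity repertoire: standing, walking (normal / slow / weak-gait
styles, optionally running), sitting on a chair or on the floor,
deliberately lying on the floor, picking an object off the floor, and
three fall modes (forward from standing/walking, from a chair, and a
collapse while trying to sit down).  Deliberate lying descents take
3.7–4 s; falls take 1.3–1.9 s (from-chair falls 1.0–1.5 s, consistent
with the lower start height) and contain a rapid collapse phase —
the kinematic signature that separates a fall from a controlled
descent.

Weak gait is modelled as unequal left/right step lengths (the foot
separation plateaus at the stepping foot's step length), a quasi-static
lateral trunk lean, and slow balance-correcting lateral arm excursions;
these are exactly the features the risk-assessment factors estimate, so
parameter-recovery tests can compare the estimate with the configured
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .types import (
    JOINT_NAMES,
    AccelerationSeries,
    FloorPlane,
    JointPosition,
    SkeletonFrame,
    SkeletonStream,
    TrackingState,
)

__all__ = [
    "GaitParams",
    "MotionScript",
    "Segment",
    "GAIT_PRESETS",
    "simulate",
    "standard_suite",
    "accelerometer_from_stream",
    "ScriptError",
]

_GRAVITY = 9.81


class ScriptError(ValueError):
    """A motion script references an unknown activity or bad parameters."""


@dataclass(frozen=True)
class GaitParams:
    step_length_l: float = 0.35   # m
    step_length_r: float = 0.35   # m
    sway_amp: float = 0.02        # m, oscillatory lateral trunk sway
    sway_lean: float = 0.0        # m, quasi-static lateral lean
    arm_spread_amp: float = 0.0   # m, lateral balance-correction arm excursion
    cadence: float = 1.6          # steps/s
    noise_sd: float = 0.01        # m, per-joint Gaussian jitter
    bob_amp: float = 0.03         # m, vertical head fluctuation while walking

    @property
    def asymmetry(self) -> float:
        return abs(self.step_length_r - self.step_length_l)


GAIT_PRESETS: dict[str, GaitParams] = {
    "normal": GaitParams(),
    "slow": GaitParams(step_length_l=0.25, step_length_r=0.25, cadence=1.2, bob_amp=0.02),
    "weak": GaitParams(
        step_length_l=0.25,
        step_length_r=0.45,
        sway_amp=0.03,
        sway_lean=0.10,
        arm_spread_amp=0.25,
        cadence=1.4,
        bob_amp=0.02,
    ),
}

ACTIVITIES = (
    "stand",
    "walk",
    "run",
    "sit_chair",
    "sit_floor",
    "lie_floor",
    "pick_object",
    "fall_forward",
    "fall_from_chair",
    "fall_while_sitting_down",
)

_FALL_ACTIVITIES = {"fall_forward", "fall_from_chair", "fall_while_sitting_down"}


@dataclass(frozen=True)
class Segment:
    activity: str
    duration: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ScriptError(f"unknown activity {self.activity!r}")
        if self.duration <= 0:
            raise ScriptError("segment duration must be positive")


@dataclass(frozen=True)
class MotionScript:
    segments: tuple[Segment, ...]
    gait: GaitParams = field(default_factory=GaitParams)
    seed: int = 0
    fps: float = 30.0
    camera_height: float = 0.91   # m, ~3 ft sensor placement
    axis: str = "x"               # movement axis: 'x' (across view) or 'z' (depth)

    @staticmethod
    def from_dict(data: dict[str, Any]) -> "MotionScript":
        gait_data = data.get("gait", "normal")
        if isinstance(gait_data, str):
            gait = GAIT_PRESETS[gait_data]
        else:
            preset = gait_data.pop("preset", None)
            base = GAIT_PRESETS[preset] if preset else GaitParams()
            gait = replace(base, **gait_data)
        segments = tuple(
            Segment(s["activity"], float(s["duration"]), dict(s.get("params", {})))
            for s in data["segments"]
        )
        return MotionScript(
            segments=segments,
            gait=gait,
            seed=int(data.get("seed", 0)),
            fps=float(data.get("fps", 30.0)),
            camera_height=float(data.get("camera_height", 0.91)),
            axis=str(data.get("axis", "x")),
        )

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"activity": s.activity, "duration": s.duration, "params": s.params}
                for s in self.segments
            ],
            "gait": {
                "step_length_l": self.gait.step_length_l,
                "step_length_r": self.gait.step_length_r,
                "sway_amp": self.gait.sway_amp,
                "sway_lean": self.gait.sway_lean,
                "arm_spread_amp": self.gait.arm_spread_amp,
                "cadence": self.gait.cadence,
                "noise_sd": self.gait.noise_sd,
                "bob_amp": self.gait.bob_amp,
            },
            "seed": self.seed,
            "fps": self.fps,
            "camera_height": self.camera_height,
            "axis": self.axis,
        }


# ---------------------------------------------------------------------------
# posture templates: joint -> (u forward, v lateral, h height), meters.
# Lateral signs: the subject's right is +v.

def _posture(entries: dict[str, tuple[float, float, float]]) -> np.ndarray:
    arr = np.zeros((len(JOINT_NAMES), 3))
    for i, name in enumerate(JOINT_NAMES):
        arr[i] = entries[name]
    return arr


_STAND = _posture({
    "head": (0.0, 0.0, 1.50),
    "shoulder_center": (0.0, 0.0, 1.35),
    "torso": (0.0, 0.0, 1.10),
    "hip_center": (0.0, 0.0, 0.95),
    "shoulder_l": (0.0, -0.18, 1.35), "shoulder_r": (0.0, 0.18, 1.35),
    "elbow_l": (0.0, -0.22, 1.15), "elbow_r": (0.0, 0.22, 1.15),
    "wrist_l": (0.0, -0.24, 1.00), "wrist_r": (0.0, 0.24, 1.00),
    "hand_l": (0.0, -0.25, 0.95), "hand_r": (0.0, 0.25, 0.95),
    "hip_l": (0.0, -0.12, 0.95), "hip_r": (0.0, 0.12, 0.95),
    "knee_l": (0.0, -0.12, 0.50), "knee_r": (0.0, 0.12, 0.50),
    "ankle_l": (0.0, -0.12, 0.10), "ankle_r": (0.0, 0.12, 0.10),
    "foot_l": (0.05, -0.12, 0.05), "foot_r": (0.05, 0.12, 0.05),
})

_SIT_CHAIR = _posture({
    "head": (0.0, 0.0, 1.05),
    "shoulder_center": (0.0, 0.0, 0.92),
    "torso": (0.0, 0.0, 0.75),
    "hip_center": (0.0, 0.0, 0.55),
    "shoulder_l": (0.0, -0.18, 0.92), "shoulder_r": (0.0, 0.18, 0.92),
    "elbow_l": (0.05, -0.22, 0.75), "elbow_r": (0.05, 0.22, 0.75),
    "wrist_l": (0.15, -0.22, 0.62), "wrist_r": (0.15, 0.22, 0.62),
    "hand_l": (0.20, -0.22, 0.60), "hand_r": (0.20, 0.22, 0.60),
    "hip_l": (0.0, -0.12, 0.55), "hip_r": (0.0, 0.12, 0.55),
    "knee_l": (0.30, -0.12, 0.45), "knee_r": (0.30, 0.12, 0.45),
    "ankle_l": (0.35, -0.12, 0.10), "ankle_r": (0.35, 0.12, 0.10),
    "foot_l": (0.42, -0.12, 0.05), "foot_r": (0.42, 0.12, 0.05),
})

_SIT_FLOOR = _posture({
    "head": (0.0, 0.0, 0.65),
    "shoulder_center": (0.0, 0.0, 0.52),
    "torso": (0.0, 0.0, 0.38),
    "hip_center": (0.0, 0.0, 0.12),
    "shoulder_l": (0.0, -0.18, 0.52), "shoulder_r": (0.0, 0.18, 0.52),
    "elbow_l": (0.05, -0.20, 0.38), "elbow_r": (0.05, 0.20, 0.38),
    "wrist_l": (0.12, -0.20, 0.25), "wrist_r": (0.12, 0.20, 0.25),
    "hand_l": (0.18, -0.20, 0.22), "hand_r": (0.18, 0.20, 0.22),
    "hip_l": (0.0, -0.12, 0.12), "hip_r": (0.0, 0.12, 0.12),
    "knee_l": (0.30, -0.14, 0.25), "knee_r": (0.30, 0.14, 0.25),
    "ankle_l": (0.50, -0.13, 0.10), "ankle_r": (0.50, 0.13, 0.10),
    "foot_l": (0.60, -0.13, 0.08), "foot_r": (0.60, 0.13, 0.08),
})

_LIE = _posture({
    "head": (0.70, 0.0, 0.18),
    "shoulder_center": (0.50, 0.0, 0.16),
    "torso": (0.30, 0.0, 0.15),
    "hip_center": (0.0, 0.0, 0.12),
    "shoulder_l": (0.50, -0.18, 0.16), "shoulder_r": (0.50, 0.18, 0.16),
    "elbow_l": (0.40, -0.25, 0.12), "elbow_r": (0.40, 0.25, 0.12),
    "wrist_l": (0.30, -0.28, 0.10), "wrist_r": (0.30, 0.28, 0.10),
    "hand_l": (0.25, -0.30, 0.10), "hand_r": (0.25, 0.30, 0.10),
    "hip_l": (0.0, -0.12, 0.12), "hip_r": (0.0, 0.12, 0.12),
    "knee_l": (-0.40, -0.13, 0.12), "knee_r": (-0.40, 0.13, 0.12),
    "ankle_l": (-0.80, -0.13, 0.10), "ankle_r": (-0.80, 0.13, 0.10),
    "foot_l": (-0.90, -0.13, 0.08), "foot_r": (-0.90, 0.13, 0.08),
})

_CROUCH = _posture({
    "head": (0.20, 0.0, 0.75),
    "shoulder_center": (0.15, 0.0, 0.65),
    "torso": (0.05, 0.0, 0.55),
    "hip_center": (-0.10, 0.0, 0.50),
    "shoulder_l": (0.15, -0.18, 0.65), "shoulder_r": (0.15, 0.18, 0.65),
    "elbow_l": (0.25, -0.20, 0.45), "elbow_r": (0.25, 0.20, 0.45),
    "wrist_l": (0.32, -0.18, 0.25), "wrist_r": (0.32, 0.18, 0.25),
    "hand_l": (0.35, -0.16, 0.15), "hand_r": (0.35, 0.16, 0.15),
    "hip_l": (-0.10, -0.12, 0.50), "hip_r": (-0.10, 0.12, 0.50),
    "knee_l": (0.10, -0.13, 0.30), "knee_r": (0.10, 0.13, 0.30),
    "ankle_l": (0.05, -0.12, 0.10), "ankle_r": (0.05, 0.12, 0.10),
    "foot_l": (0.12, -0.12, 0.05), "foot_r": (0.12, 0.12, 0.05),
})

_TARGETS = {
    "stand": _STAND, "walk": _STAND, "run": _STAND,
    "sit_chair": _SIT_CHAIR, "sit_floor": _SIT_FLOOR, "lie_floor": _LIE,
    "fall_forward": _LIE, "fall_from_chair": _LIE,
    "fall_while_sitting_down": _LIE,
}

_J = {name: i for i, name in enumerate(JOINT_NAMES)}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _fall_profile(u: np.ndarray) -> np.ndarray:
    """Three-phase fall blend: slow balance loss, rapid collapse, settle."""
    b = np.empty_like(u)
    m1 = u < 0.35
    m2 = (u >= 0.35) & (u < 0.70)
    m3 = u >= 0.70
    b[m1] = 0.12 * _smoothstep(u[m1] / 0.35)
    b[m2] = 0.12 + 0.80 * _smoothstep((u[m2] - 0.35) / 0.35)
    b[m3] = 0.92 + 0.08 * _smoothstep((u[m3] - 0.70) / 0.30)
    return b


def _sit_collapse_profile(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Blend weights (toward sit_floor, toward lie) for a collapse while
    sitting down: a controlled partial sit for ~70% of the segment, then
    a rapid collapse through to lying."""
    w_sit = np.where(u < 0.72, 0.8 * _smoothstep(u / 0.72), 0.8)
    w_lie = np.where(u >= 0.72, _smoothstep((u - 0.72) / 0.28), 0.0)
    return w_sit * (1.0 - w_lie), w_lie


def _gait_overlay(
    pose: np.ndarray,
    t_local: np.ndarray,
    phase0: float,
    gait: GaitParams,
    advance_speed: float,
    lean_sign: float,
) -> np.ndarray:
    """Add walking dynamics on top of a standing pose array (n, J, 3)."""
    out = pose.copy()
    stride_freq = gait.cadence / 2.0   # strides/s
    phi = 2.0 * np.pi * stride_freq * t_local + phase0

    # forward advance for the whole body
    out[:, :, 0] += advance_speed * t_local[:, None]

    # feet: plateaued separation wave; plateau = the stepping foot's step
    # length, so |separation| at mid-stance equals the step length
    s = np.sin(phi)
    wave = np.clip(s / 0.55, -1.0, 1.0)
    amp = np.where(s > 0, gait.step_length_r, gait.step_length_l)
    sep = wave * amp
    out[:, _J["foot_r"], 0] += sep / 2.0
    out[:, _J["foot_l"], 0] -= sep / 2.0
    out[:, _J["ankle_r"], 0] += sep / 2.0
    out[:, _J["ankle_l"], 0] -= sep / 2.0
    # slight foot lift during swing
    lift = 0.04 * np.clip(np.abs(np.sin(phi)) - 0.55, 0.0, None) / 0.45
    out[:, _J["foot_r"], 2] += np.where(np.cos(phi) * s < 0, lift, 0.0)
    out[:, _J["foot_l"], 2] += np.where(np.cos(phi) * s > 0, lift, 0.0)

    # trunk: quasi-static lean plus stride-periodic sway
    sway = lean_sign * gait.sway_lean + gait.sway_amp * np.sin(phi)
    for j in ("torso", "shoulder_center", "head"):
        out[:, _J[j], 1] += sway * (1.0 if j == "torso" else 0.8)

    # head bob, twice per stride
    out[:, _J["head"], 2] += gait.bob_amp * np.sin(2.0 * phi + 0.4)
    out[:, _J["shoulder_center"], 2] += 0.6 * gait.bob_amp * np.sin(2.0 * phi + 0.4)

    # arm swing (forward) and balance-correcting lateral spread
    swing = 0.15 * np.sin(phi)
    for jr, jl in (("hand_r", "hand_l"), ("wrist_r", "wrist_l"), ("elbow_r", "elbow_l")):
        out[:, _J[jr], 0] += swing
        out[:, _J[jl], 0] -= swing
    if gait.arm_spread_amp > 0:
        flail = gait.arm_spread_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * 0.4 * t_local + phase0))
        for jr, jl in (("hand_r", "hand_l"), ("wrist_r", "wrist_l")):
            out[:, _J[jr], 1] += flail
            out[:, _J[jl], 1] -= flail
    return out


def simulate(script: MotionScript) -> tuple[SkeletonStream, pd.DataFrame]:
    """Render a motion script into a skeleton stream plus a per-frame
    ground-truth label track (columns: frame, t, activity, is_fall).

    Deterministic given the script (including its seed).
    """
    rng = np.random.default_rng(script.seed)
    fps = script.fps
    lean_sign = 1.0 if rng.random() < 0.5 else -1.0
    gait_phase = float(rng.uniform(0, 2 * np.pi))

    current = _STAND.copy()          # absolute pose of the last rendered frame
    origin = 0.0                     # absolute forward position of the hip anchor
    poses: list[np.ndarray] = []
    labels: list[tuple[str, bool]] = []

    def _anchored(template: np.ndarray) -> np.ndarray:
        t = template.copy()
        t[:, 0] += origin
        return t

    for seg in script.segments:
        n = max(2, int(round(seg.duration * fps)))
        t_local = np.arange(n) / fps
        u = t_local / seg.duration
        gait = script.gait
        if seg.activity in ("walk", "run"):
            if seg.activity == "run":
                gait = replace(gait, cadence=2.6, step_length_l=0.8,
                               step_length_r=0.8, bob_amp=0.05)
            speed = float(seg.params.get(
                "speed", gait.cadence * (gait.step_length_l + gait.step_length_r) / 2.0
            ))
            target = _anchored(_STAND)
            base = current[None, :, :] + _smoothstep(t_local[:, None, None] / 0.5) * (
                target[None, :, :] - current[None, :, :]
            )
            pose = _gait_overlay(base, t_local, gait_phase, gait, speed, lean_sign)
            gait_phase += 2.0 * np.pi * (gait.cadence / 2.0) * seg.duration
        elif seg.activity in ("stand", "sit_chair", "sit_floor", "lie_floor"):
            target = _anchored(_TARGETS[seg.activity])
            default_tr = {"stand": 0.8, "sit_chair": 2.0,
                          "sit_floor": 3.4, "lie_floor": 3.85}[seg.activity]
            transition = float(seg.params.get("transition", min(default_tr, seg.duration)))
            b = _smoothstep(t_local / transition)[:, None, None]
            pose = current[None, :, :] + b * (target[None, :, :] - current[None, :, :])
            # small idle sway while holding
            idle = 0.005 * np.sin(2 * np.pi * 0.3 * t_local + gait_phase)
            pose[:, _J["torso"], 1] += idle
        elif seg.activity == "pick_object":
            b = _smoothstep(2.0 * np.minimum(u, 1.0 - u))[:, None, None]
            pose = current[None, :, :] + b * (_anchored(_CROUCH)[None, :, :] - current[None, :, :])
        elif seg.activity in ("fall_forward", "fall_from_chair"):
            b = _fall_profile(u)[:, None, None]
            pose = current[None, :, :] + b * (_anchored(_LIE)[None, :, :] - current[None, :, :])
        elif seg.activity == "fall_while_sitting_down":
            w_sit, w_lie = _sit_collapse_profile(u)
            pose = (
                (1.0 - w_sit - w_lie)[:, None, None] * current[None, :, :]
                + w_sit[:, None, None] * _anchored(_SIT_FLOOR)[None, :, :]
                + w_lie[:, None, None] * _anchored(_LIE)[None, :, :]
            )
        else:  # pragma: no cover - guarded by Segment validation
            raise ScriptError(f"unknown activity {seg.activity!r}")

        current = pose[-1].copy()
        origin = float(current[_J["hip_center"], 0])
        poses.append(pose)
        labels.extend([(seg.activity, seg.activity in _FALL_ACTIVITIES)] * n)

    world = np.concatenate(poses, axis=0)
    nf = world.shape[0]
    world = world + rng.normal(0.0, script.gait.noise_sd, size=world.shape)

    # map world (u forward, v lateral, h up) into sensor coordinates
    u_span = world[:, :, 0]
    if script.axis == "x":
        x = u_span - (u_span.max() + u_span.min()) / 2.0
        z = 2.5 + world[:, :, 1]
    else:
        z = (u_span.max() - u_span) + 1.0
        x = world[:, :, 1]
    z = np.clip(z, 0.05, None)
    y = world[:, :, 2] - script.camera_height

    floor = FloorPlane(0.0, 1.0, 0.0, script.camera_height)
    frames = []
    for i in range(nf):
        joints = {
            name: JointPosition(
                float(x[i, j]), float(y[i, j]), float(z[i, j]), TrackingState.TRACKED
            )
            for j, name in enumerate(JOINT_NAMES)
        }
        frames.append(SkeletonFrame(i, i / fps, joints, floor))
    stream = SkeletonStream(
        frames,
        metadata={
            "source": "fallsense.simulator",
            "fps": fps,
            "camera_height": script.camera_height,
            "seed": script.seed,
        },
    )
    label_df = pd.DataFrame(
        {
            "frame": np.arange(nf),
            "t": np.arange(nf) / fps,
            "activity": [a for a, _ in labels],
            "is_fall": [f for _, f in labels],
        }
    )
    return stream, label_df


def accelerometer_from_stream(
    stream: SkeletonStream, noise_sd: float = 0.2, seed: int = 0
) -> AccelerationSeries:
    """Emulate a body-worn accelerometer-magnitude trace from the head
    trajectory: |g + d2h/dt2| plus Gaussian sensor noise."""
    rng = np.random.default_rng(seed)
    t = np.array([f.timestamp for f in stream])
    h = np.array([
        f.joint("head").y + f.floor.D if f.joint("head").usable else np.nan
        for f in stream
    ])
    # double differentiation amplifies jitter by fps^2, so smooth hard
    # (median + boxcar) and use a wide second-difference stencil
    h = pd.Series(h).rolling(5, min_periods=1, center=True).median()
    h = h.rolling(9, min_periods=1, center=True).mean().to_numpy()
    k = 5
    acc = np.zeros_like(h)
    if len(h) > 2 * k:
        acc[k:-k] = (h[2 * k:] - 2 * h[k:-k] + h[:-2 * k]) * (stream.fps / k) ** 2
    mag = np.abs(_GRAVITY + acc) + rng.normal(0.0, noise_sd, size=len(h))
    return AccelerationSeries(list(t), list(np.abs(mag)))


# ---------------------------------------------------------------------------
# the standard 30-fall / 40-ADL suite


def _walk_style(rng: np.random.Generator) -> GaitParams:
    style = rng.choice(["normal", "slow", "weak"], p=[0.5, 0.25, 0.25])
    return GAIT_PRESETS[str(style)]


def standard_suite(seed: int) -> list[tuple[SkeletonStream, pd.DataFrame]]:
    """A 70-sequence benchmark: 30 falls and 40 activities of daily
    life, with scenario parameters drawn from documented ranges.
    Deterministic per seed; each stream's metadata carries its scenario
    name and sequence label."""
    rng = np.random.default_rng(seed)
    scripts: list[tuple[str, MotionScript]] = []

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    # --- 30 falls
    for _ in range(12):
        scripts.append(("fall_forward", MotionScript(
            segments=(
                Segment("walk", float(rng.uniform(2.0, 3.5))),
                Segment("fall_forward", float(rng.uniform(1.3, 1.9))),
                Segment("lie_floor", 3.0),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(9):
        scripts.append(("fall_from_chair", MotionScript(
            segments=(
                Segment("stand", 1.5),
                Segment("sit_chair", 2.5, {"transition": 2.0}),
                Segment("fall_from_chair", float(rng.uniform(1.0, 1.5))),
                Segment("lie_floor", 3.0),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(9):
        scripts.append(("fall_while_sitting_down", MotionScript(
            segments=(
                Segment("walk", float(rng.uniform(2.0, 3.0))),
                Segment("fall_while_sitting_down", float(rng.uniform(1.8, 2.4))),
                Segment("lie_floor", 3.0),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))

    # --- 40 activities of daily life
    for _ in range(14):
        scripts.append(("walk", MotionScript(
            segments=(
                Segment("stand", 1.0),
                Segment("walk", float(rng.uniform(8.0, 11.0))),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(8):
        scripts.append(("sit_chair", MotionScript(
            segments=(
                Segment("walk", 2.5),
                Segment("sit_chair", 5.0, {"transition": float(rng.uniform(1.5, 2.5))}),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(6):
        scripts.append(("sit_floor", MotionScript(
            segments=(
                Segment("walk", 2.0),
                Segment("sit_floor", 6.0, {"transition": float(rng.uniform(3.0, 3.8))}),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(6):
        scripts.append(("lie_floor", MotionScript(
            segments=(
                Segment("walk", 2.0),
                Segment("lie_floor", 7.0, {"transition": float(rng.uniform(3.7, 4.0))}),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))
    for _ in range(6):
        scripts.append(("pick_object", MotionScript(
            segments=(
                Segment("walk", 2.5),
                Segment("pick_object", float(rng.uniform(2.5, 3.5))),
                Segment("walk", 2.5),
            ),
            gait=_walk_style(rng), seed=sub_seed(),
            axis=str(rng.choice(["x", "z"])),
        )))

    out = []
    for name, script in scripts:
        stream, label_df = simulate(script)
        stream.metadata["scenario"] = name
        stream.metadata["is_fall_sequence"] = bool(label_df["is_fall"].any())
        out.append((stream, label_df))
    return out
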