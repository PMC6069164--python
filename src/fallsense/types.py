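"""Domain types for depth-sensor skeleton streams and floor geometry.

Coordinate convention throughout the package: metric sensor space with
x to the subject's right (from the camera's view), y up, z pointing away
from the sensor.  The floor is described by the plane coefficients
``(A, B, C, D)`` the sensor reports as its floor clipping vector, with D
the camera height above the floor in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

__all__ = [
    "TrackingState",
    "JointPosition",
    "FloorPlane",
    "SkeletonFrame",
    "SkeletonStream",
    "AccelerationSeries",
    "JOINT_NAMES",
    "KEY_JOINTS",
    "DEFAULT_JOINT_ALIASES",
    "ValidationError",
    "FormatError",
    "UnavailableValue",
]

#: Kinect-v1 style 20-joint vocabulary.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "shoulder_center",
    "torso",
    "hip_center",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
    "foot_l",
    "foot_r",
)

#: Joints that must be tracked for a subject to count as detected.
KEY_JOINTS: tuple[str, ...] = ("head", "shoulder_center", "hip_center")

#: Role → joint-name aliases used by the gait-factor formulas.  The "arm"
#: of the arm-spread measure is the distal hand joint; the "torso" role is
#: the spine joint.  Override via RiskConfig.joint_aliases.
DEFAULT_JOINT_ALIASES: dict[str, str] = {
    "arm_l": "hand_l",
    "arm_r": "hand_r",
    "torso": "torso",
}


class ValidationError(ValueError):
    """A stream or frame violates a structural invariant."""


class FormatError(ValueError):
    """An on-disk file does not match the documented layout."""


class UnavailableValue(Exception):
    """A derived quantity cannot be computed (e.g. untracked joint)."""


class TrackingState(str, Enum):
    TRACKED = "tracked"
    INFERRED = "inferred"
    NOT_TRACKED = "not_tracked"


@dataclass(frozen=True)
class JointPosition:
    """One joint's 3-D position in sensor space (meters)."""

    x: float
    y: float
    z: float
    tracking_state: TrackingState = TrackingState.TRACKED

    def __post_init__(self) -> None:
        if self.tracking_state is not TrackingState.NOT_TRACKED:
            if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
                raise ValidationError(
                    "tracked/inferred joint coordinates must be finite"
                )

    @property
    def usable(self) -> bool:
        return self.tracking_state is not TrackingState.NOT_TRACKED

    @staticmethod
    def untracked() -> "JointPosition":
        return JointPosition(
            float("nan"), float("nan"), float("nan"), TrackingState.NOT_TRACKED
        )


@dataclass(frozen=True)
class FloorPlane:
    """Floor plane Ax + By + Cz + D = 0; D is the camera height (m)."""

    A: float
    B: float
    C: float
    D: float

    def __post_init__(self) -> None:
        if self.A ** 2 + self.B ** 2 + self.C ** 2 <= 0.0:
            raise ValidationError("degenerate floor plane: A=B=C=0")
        if self.D < 0:
            raise ValidationError("camera height D must be non-negative")

    @property
    def normal_length(self) -> float:
        return math.sqrt(self.A ** 2 + self.B ** 2 + self.C ** 2)


@dataclass
class SkeletonFrame:
    """One time-stamped snapshot of the 20 named joints plus the floor."""

    frame_index: int
    timestamp: float
    joints: Mapping[str, JointPosition]
    floor: FloorPlane

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError("frame_index must be non-negative")
        unknown = set(self.joints) - set(JOINT_NAMES)
        if unknown:
            raise ValidationError(f"unknown joint names: {sorted(unknown)}")

    def joint(self, name: str) -> JointPosition:
        return self.joints.get(name, JointPosition.untracked())

    def tracked(self, *names: str) -> bool:
        return all(self.joint(n).usable for n in names)


@dataclass
class SkeletonStream:
    """An ordered sequence of frames with acquisition metadata."""

    frames: list[SkeletonFrame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("timestamps must strictly increase")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame_index must strictly increase")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> SkeletonFrame:
        return self.frames[i]

    @property
    def fps(self) -> float:
        return float(self.metadata.get("fps", 30.0))

    def gap_indices(self, tolerance: float = 0.2) -> list[int]:
        """Positions i where the spacing t[i]-t[i-1] deviates from 1/fps
        by more than ``tolerance`` (fractional).  Gaps are permitted but
        flagged before kinematics are trusted."""
        nominal = 1.0 / self.fps
        out = []
        for i in range(1, len(self.frames)):
            dt = self.frames[i].timestamp - self.frames[i - 1].timestamp
            if abs(dt - nominal) > tolerance * nominal:
                out.append(i)
        return out


@dataclass
class AccelerationSeries:
    """Accelerometer magnitude samples in SI units (m/s^2)."""

    timestamps: list[float]
    magnitude: list[float]

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.magnitude):
            raise ValidationError("timestamps and magnitude differ in length")
        if any(b < a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValidationError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)
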