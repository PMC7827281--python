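"""25-joint skeletal data model and the vector/angle primitives built on it.

The skeleton follows the standard 25-joint set produced by consumer
depth-sensing SDKs.  Coordinates are camera space, in meters, right-handed:
origin at the sensor, +y up, +z pointing from the sensor toward the user,
+x completing the triad.  Only two primitives depend on the convention:
``torso_tilt`` (vertical = +y) and the anteroposterior knee-over-toe check
in :mod:`gerofit.assessment` (depth = z).  The user is assumed to face the
sensor.

A frame whose joints leave the sensor's depth working range of 0.4–4.5 m is
flagged out-of-range rather than dropped; downstream assessment refuses
streams with more than 10 % flagged frames.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping

import numpy as np

from .errors import DegeneratePoseError, InputError

# ---------------------------------------------------------------------------
# Configuration constants
# ---------------------------------------------------------------------------

#: Sensor depth working range in meters; joints outside flag the frame.
DEPTH_RANGE_M: tuple[float, float] = (0.4, 4.5)

#: Nominal skeletal update rate of the sensor, frames per second.
DEFAULT_FRAME_RATE_HZ: float = 30.0

#: Assessment refuses streams with more than this fraction of flagged frames.
MAX_OUT_OF_RANGE_FRACTION: float = 0.10

Side = Literal["left", "right"]


class JointId(enum.IntEnum):
    """The 25 tracked joints, in the sensor SDK's canonical order."""

    SPINE_BASE = 0
    SPINE_MID = 1
    NECK = 2
    HEAD = 3
    SHOULDER_LEFT = 4
    ELBOW_LEFT = 5
    WRIST_LEFT = 6
    HAND_LEFT = 7
    SHOULDER_RIGHT = 8
    ELBOW_RIGHT = 9
    WRIST_RIGHT = 10
    HAND_RIGHT = 11
    HIP_LEFT = 12
    KNEE_LEFT = 13
    ANKLE_LEFT = 14
    FOOT_LEFT = 15
    HIP_RIGHT = 16
    KNEE_RIGHT = 17
    ANKLE_RIGHT = 18
    FOOT_RIGHT = 19
    SPINE_SHOULDER = 20
    HAND_TIP_LEFT = 21
    THUMB_LEFT = 22
    HAND_TIP_RIGHT = 23
    THUMB_RIGHT = 24


N_JOINTS = len(JointId)  # 25


def _coerce_joint(j: "JointId | str | int") -> JointId:
    try:
        if isinstance(j, str):
            return JointId[j]
        return JointId(j)
    except (KeyError, ValueError) as exc:
        raise InputError(f"unknown joint identifier: {j!r}") from exc


def side_joints(side: Side) -> dict[str, JointId]:
    """Map role names to the joints of one body side."""
    if side not in ("left", "right"):
        raise InputError(f"side must be 'left' or 'right', got {side!r}")
    s = side.upper()
    return {
        "shoulder": JointId[f"SHOULDER_{s}"],
        "elbow": JointId[f"ELBOW_{s}"],
        "wrist": JointId[f"WRIST_{s}"],
        "hand": JointId[f"HAND_{s}"],
        "hip": JointId[f"HIP_{s}"],
        "knee": JointId[f"KNEE_{s}"],
        "ankle": JointId[f"ANKLE_{s}"],
        "foot": JointId[f"FOOT_{s}"],
    }


# ---------------------------------------------------------------------------
# Frame and stream containers
# ---------------------------------------------------------------------------


@dataclass
class SkeletalFrame:
    """One timestamped snapshot of all 25 joint positions (meters).

    ``positions`` is a ``(25, 3)`` float array indexed by :class:`JointId`.
    """

    timestamp: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (N_JOINTS, 3):
            raise InputError(
                f"frame must hold {N_JOINTS} joints with 3 coordinates, "
                f"got array of shape {self.positions.shape}"
            )

    @classmethod
    def from_mapping(
        cls, timestamp: float, positions: Mapping["JointId | str", Iterable[float]]
    ) -> "SkeletalFrame":
        if len(positions) != N_JOINTS:
            raise InputError(
                f"frame requires all {N_JOINTS} joints, got {len(positions)}"
            )
        arr = np.empty((N_JOINTS, 3), dtype=float)
        for key, value in positions.items():
            arr[_coerce_joint(key)] = np.asarray(value, dtype=float)
        return cls(timestamp, arr)

    def position(self, joint: "JointId | str") -> np.ndarray:
        return self.positions[_coerce_joint(joint)]

    __getitem__ = position

    @property
    def out_of_range(self) -> bool:
        """True if any joint depth (z) lies outside the sensor working range."""
        z = self.positions[:, 2]
        return bool((z < DEPTH_RANGE_M[0]).any() or (z > DEPTH_RANGE_M[1]).any())


@dataclass
class FrameStream:
    """Ordered sequence of frames with strictly increasing timestamps."""

    frames: list[SkeletalFrame] = field(default_factory=list)
    nominal_rate: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise InputError(f"nominal_rate must be > 0, got {self.nominal_rate}")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InputError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletalFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> SkeletalFrame:
        return self.frames[i]

    @property
    def duration(self) -> float:
        """Elapsed time between first and last frame, seconds."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp - self.frames[0].timestamp

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def as_array(self) -> np.ndarray:
        """Positions stacked as ``(n_frames, 25, 3)``."""
        return np.stack([f.positions for f in self.frames])

    def out_of_range_fraction(self) -> float:
        if not self.frames:
            return 0.0
        return sum(f.out_of_range for f in self.frames) / len(self.frames)


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise DegeneratePoseError("angle undefined for a zero-length segment")
    cosine = float(np.dot(u, v)) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def segment(
    frame: SkeletalFrame, a: "JointId | str", b: "JointId | str"
) -> tuple[np.ndarray, float]:
    """Displacement vector a→b and its Euclidean length in meters."""
    ja, jb = _coerce_joint(a), _coerce_joint(b)
    if ja == jb:
        raise InputError("segment endpoints must be distinct joints")
    vec = frame.positions[jb] - frame.positions[ja]
    return vec, float(np.linalg.norm(vec))


def joint_angle(
    frame: SkeletalFrame,
    a: "JointId | str",
    vertex: "JointId | str",
    c: "JointId | str",
) -> float:
    """Interior angle at ``vertex`` between vertex→a and vertex→c, degrees.

    Result lies in [0, 180].  Raises :class:`DegeneratePoseError` when either
    segment has zero length.
    """
    ja, jv, jc = _coerce_joint(a), _coerce_joint(vertex), _coerce_joint(c)
    if len({ja, jv, jc}) != 3:
        raise InputError("joint_angle requires three distinct joints")
    u = frame.positions[ja] - frame.positions[jv]
    v = frame.positions[jc] - frame.positions[jv]
    return _angle_between_deg(u, v)


def torso_tilt(frame: SkeletalFrame) -> float:
    """Angle in degrees between the SPINE_BASE→SPINE_SHOULDER axis and
    world-vertical (+y).  0° for a perfectly upright torso."""
    spine = frame.positions[JointId.SPINE_SHOULDER] - frame.positions[JointId.SPINE_BASE]
    if np.linalg.norm(spine) == 0.0:
        raise DegeneratePoseError("coincident spine joints")
    return _angle_between_deg(spine, np.array([0.0, 1.0, 0.0]))


def arm_elevation(frame: SkeletalFrame, side: Side) -> float:
    """Angle of the arm with respect to the body, degrees.

    Measured between the shoulder→wrist vector and the downward torso axis
    (SPINE_SHOULDER→SPINE_BASE), so a compensatory torso tilt does not
    inflate the reading.  0° with the arm hanging along the trunk; 90° with
    the arm horizontal; the achievement measure for shoulder abduction and
    flexion.
    """
    joints = side_joints(side)
    arm = frame.positions[joints["wrist"]] - frame.positions[joints["shoulder"]]
    down = frame.positions[JointId.SPINE_BASE] - frame.positions[JointId.SPINE_SHOULDER]
    return _angle_between_deg(arm, down)


def knee_flexion(frame: SkeletalFrame, side: Side) -> float:
    """Angle at the knee between thigh and lower leg, degrees.

    180° standing upright (hip, knee, ankle collinear); 90° with the thighs
    parallel to the floor at full squat depth.
    """
    joints = side_joints(side)
    return joint_angle(frame, joints["hip"], joints["knee"], joints["ankle"])
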