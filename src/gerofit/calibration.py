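"""Biometric calibration: resting posture capture and goal-coordinate geometry.

Every exercise starts from a short capture of the user standing relaxed in
front of the sensor.  The per-joint mean over that window defines the
resting state; the limb vectors derived from it (arm SE, forearm EW, thigh
HK, shank KA) are user-specific and reused across sessions.  The goal
coordinate of an angular exercise is the endpoint of the straight upper
limb rotated by the target angle from the downward resting direction within
the user's frontal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import CalibrationError, CaptureError, InputError
from .skeleton import (
    MAX_OUT_OF_RANGE_FRACTION,
    N_JOINTS,
    FrameStream,
    JointId,
    SkeletalFrame,
    Side,
    arm_elevation,
    knee_flexion,
    side_joints,
)

#: Per-joint resultant positional standard deviation above which the user is
#: considered to be moving during calibration.  2 cm is generous for elderly
#: postural sway.
STATIONARITY_THRESHOLD_M: float = 0.02

#: Minimum calibration capture length in seconds at the nominal rate.
MIN_CALIBRATION_S: float = 1.0

PROFILE_FORMAT_VERSION = 1


@dataclass
class BiometricProfile:
    """User-specific resting geometry captured at calibration."""

    user_id: str
    side: Side
    resting_positions: np.ndarray  # (25, 3) meters
    arm_vector: np.ndarray  # shoulder→elbow (SE)
    forearm_vector: np.ndarray  # elbow→wrist (EW)
    thigh_vector: np.ndarray  # hip→knee (HK)
    shank_vector: np.ndarray  # knee→ankle (KA)
    upper_limb_length: float  # |SE| + |EW|
    lower_limb_length: float  # |HK| + |KA|
    user_height: float
    resting_angles: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("upper_limb_length", "lower_limb_length", "user_height"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")

    def resting_frame(self) -> SkeletalFrame:
        """The resting posture as a frame (timestamp 0)."""
        return SkeletalFrame(0.0, self.resting_positions.copy())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "gerofit-profile",
            "version": PROFILE_FORMAT_VERSION,
            "user_id": self.user_id,
            "side": self.side,
            "upper_limb_length": float(self.upper_limb_length),
            "lower_limb_length": float(self.lower_limb_length),
            "user_height": float(self.user_height),
            "arm_vector": [float(v) for v in self.arm_vector],
            "forearm_vector": [float(v) for v in self.forearm_vector],
            "thigh_vector": [float(v) for v in self.thigh_vector],
            "shank_vector": [float(v) for v in self.shank_vector],
            "resting_angles": {k: float(v) for k, v in self.resting_angles.items()},
            "resting_positions": {
                j.name: [float(v) for v in self.resting_positions[j]] for j in JointId
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BiometricProfile":
        if doc.get("format") != "gerofit-profile":
            raise InputError("not a gerofit profile document")
        if doc.get("version") != PROFILE_FORMAT_VERSION:
            raise InputError(f"unsupported profile version {doc.get('version')!r}")
        positions = np.empty((N_JOINTS, 3))
        for name, xyz in doc["resting_positions"].items():
            positions[JointId[name]] = xyz
        return cls(
            user_id=doc["user_id"],
            side=doc["side"],
            resting_positions=positions,
            arm_vector=np.asarray(doc["arm_vector"], dtype=float),
            forearm_vector=np.asarray(doc["forearm_vector"], dtype=float),
            thigh_vector=np.asarray(doc["thigh_vector"], dtype=float),
            shank_vector=np.asarray(doc["shank_vector"], dtype=float),
            upper_limb_length=doc["upper_limb_length"],
            lower_limb_length=doc["lower_limb_length"],
            user_height=doc["user_height"],
            resting_angles=dict(doc.get("resting_angles", {})),
        )

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: "str | Path") -> "BiometricProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def calibrate(
    stream: FrameStream,
    side: Side,
    user_id: str = "anonymous",
    motion_threshold_m: float = STATIONARITY_THRESHOLD_M,
) -> BiometricProfile:
    """Estimate the resting biometric profile from a stationary capture.

    Resting joint positions are the per-joint coordinate-wise means over the
    stream; limb vectors and lengths derive from the means.  Raises
    :class:`CaptureError` when too many frames are out of depth range and
    :class:`CalibrationError` when any joint's positional standard deviation
    exceeds ``motion_threshold_m`` (the user was not stationary).
    """
    joints = side_joints(side)
    if len(stream) < MIN_CALIBRATION_S * stream.nominal_rate:
        raise InputError(
            f"calibration capture too short: {len(stream)} frames at "
            f"{stream.nominal_rate:g} Hz (need ≥ {MIN_CALIBRATION_S:g} s)"
        )
    if stream.out_of_range_fraction() > MAX_OUT_OF_RANGE_FRACTION:
        raise CaptureError(
            f"{stream.out_of_range_fraction():.0%} of frames out of depth range"
        )

    arr = stream.as_array()  # (n, 25, 3)
    sd = arr.std(axis=0)  # (25, 3)
    resultant_sd = np.sqrt((sd**2).sum(axis=1))  # (25,)
    worst = int(np.argmax(resultant_sd))
    if resultant_sd[worst] > motion_threshold_m:
        raise CalibrationError(
            f"user not stationary: joint {JointId(worst).name} moved with sd "
            f"{resultant_sd[worst] * 100:.1f} cm (threshold "
            f"{motion_threshold_m * 100:.1f} cm)"
        )

    # Anchor the mean at the first frame: exact for a perfectly static
    # stream (the deviations are identically zero there).
    mean = arr[0] + (arr - arr[0]).mean(axis=0)
    frame = SkeletalFrame(0.0, mean)
    arm = mean[joints["elbow"]] - mean[joints["shoulder"]]
    forearm = mean[joints["wrist"]] - mean[joints["elbow"]]
    thigh = mean[joints["knee"]] - mean[joints["hip"]]
    shank = mean[joints["ankle"]] - mean[joints["knee"]]
    foot_low = min(mean[JointId.FOOT_LEFT][1], mean[JointId.FOOT_RIGHT][1])
    resting_angles = {
        "arm_elevation_left": arm_elevation(frame, "left"),
        "arm_elevation_right": arm_elevation(frame, "right"),
        "knee_flexion_left": knee_flexion(frame, "left"),
        "knee_flexion_right": knee_flexion(frame, "right"),
    }
    return BiometricProfile(
        user_id=user_id,
        side=side,
        resting_positions=mean,
        arm_vector=arm,
        forearm_vector=forearm,
        thigh_vector=thigh,
        shank_vector=shank,
        upper_limb_length=float(np.linalg.norm(arm) + np.linalg.norm(forearm)),
        lower_limb_length=float(np.linalg.norm(thigh) + np.linalg.norm(shank)),
        user_height=float(mean[JointId.HEAD][1] - foot_low),
        resting_angles=resting_angles,
    )


def goal_position(profile: BiometricProfile, target_angle: float) -> np.ndarray:
    """3D coordinate of the exercise goal for an angular target.

    The point reached by the straight upper limb (length
    ``upper_limb_length``) rotated ``target_angle`` degrees from the
    downward resting direction within the user's frontal plane (camera x–y),
    anchored at the resting shoulder.  Returned at full precision; the
    5-decimal reporting precision is applied when the value is serialized.
    """
    if not 0.0 < target_angle <= 180.0:
        raise InputError(f"target_angle must lie in (0, 180], got {target_angle}")
    joints = side_joints(profile.side)
    shoulder = profile.resting_positions[joints["shoulder"]]
    spine_x = profile.resting_positions[JointId.SPINE_SHOULDER][0]
    lateral = 1.0 if shoulder[0] >= spine_x else -1.0
    theta = math.radians(target_angle)
    direction = np.array([lateral * math.sin(theta), -math.cos(theta), 0.0])
    return shoulder + profile.upper_limb_length * direction


def format_goal(point: np.ndarray) -> str:
    """Goal coordinate rendered at the system's 5-decimal reporting precision."""
    return "({:.5f}, {:.5f}, {:.5f})".format(*point)
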