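"""Seeded generators of synthetic skeletal streams and study tables.

Everything downstream (calibration, assessment, gesture recognition,
analytics) is testable without a sensor: a parametric 25-joint body model
is posed through kinematic templates — shoulder abduction, double-leg
squat, isometric scapular retraction, the horizontal swipe — with the
commanded extrema achieved exactly before noise, at the nominal 30 Hz rate.
Noise is independent Gaussian displacement per joint per frame.

``simulate_study`` emulates the deposited per-participant, per-exercise,
per-session average-angle table: group baseline + subject effect +
session × improvement + noise, with age-dependent baselines (absolute
achievement decreases with age) and age-dependent improvement steps
(session-over-session improvement increases with age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assessment import SessionRecord
from .errors import InputError
from .skeleton import (
    DEFAULT_FRAME_RATE_HZ,
    N_JOINTS,
    FrameStream,
    JointId,
    SkeletalFrame,
    Side,
)

#: Segment lengths as fractions of stature (standard anthropometric ratios).
ANTHROPOMETRIC_RATIOS = {
    "head": 0.936,
    "neck": 0.870,
    "spine_shoulder": 0.818,
    "spine_mid": 0.674,
    "spine_base": 0.530,
    "shoulder_halfwidth": 0.129,
    "hip_halfwidth": 0.0955,
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.035,
    "thigh": 0.245,
    "shank": 0.246,
    "ankle_height": 0.039,
}

#: Default distance from the sensor, meters (mid working range).
DEFAULT_DISTANCE_M = 2.5

#: Default skeletal-tracking jitter, meters (5 mm).
DEFAULT_NOISE_SD_M = 0.005


@dataclass(frozen=True)
class BodyModel:
    """Left/right-symmetric segment lengths scaled from stature."""

    height: float
    upper_arm: float
    forearm: float
    thigh: float
    shank: float
    shoulder_halfwidth: float
    spine: float  # SPINE_BASE→SPINE_SHOULDER

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise InputError(f"body segment {name} must be > 0")

    @classmethod
    def from_height(cls, height: float = 1.65) -> "BodyModel":
        r = ANTHROPOMETRIC_RATIOS
        return cls(
            height=height,
            upper_arm=r["upper_arm"] * height,
            forearm=r["forearm"] * height,
            thigh=r["thigh"] * height,
            shank=r["shank"] * height,
            shoulder_halfwidth=r["shoulder_halfwidth"] * height,
            spine=(r["spine_shoulder"] - r["spine_base"]) * height,
        )

    @property
    def tracked_height(self) -> float:
        """Vertical HEAD-joint-to-foot extent (the head joint sits at the
        head center, below the crown)."""
        return ANTHROPOMETRIC_RATIOS["head"] * self.height


_UPPER_BODY = [
    JointId.SPINE_MID, JointId.SPINE_SHOULDER, JointId.NECK, JointId.HEAD,
    JointId.SHOULDER_LEFT, JointId.ELBOW_LEFT, JointId.WRIST_LEFT,
    JointId.HAND_LEFT, JointId.HAND_TIP_LEFT, JointId.THUMB_LEFT,
    JointId.SHOULDER_RIGHT, JointId.ELBOW_RIGHT, JointId.WRIST_RIGHT,
    JointId.HAND_RIGHT, JointId.HAND_TIP_RIGHT, JointId.THUMB_RIGHT,
]

#: Camera-space x sign of each body side (the user faces the sensor).
_SIDE_SIGN = {"left": 1.0, "right": -1.0}


def rest_pose(body: BodyModel, distance_m: float = DEFAULT_DISTANCE_M) -> np.ndarray:
    """Standing rest pose, arms hanging: (25, 3) joint positions."""
    h, z0 = body.height, distance_m
    r = ANTHROPOMETRIC_RATIOS
    p = np.zeros((N_JOINTS, 3))
    p[:, 2] = z0

    p[JointId.SPINE_BASE, 1] = r["spine_base"] * h
    p[JointId.SPINE_MID, 1] = r["spine_mid"] * h
    p[JointId.SPINE_SHOULDER, 1] = r["spine_shoulder"] * h
    p[JointId.NECK, 1] = r["neck"] * h
    p[JointId.HEAD, 1] = r["head"] * h

    for side, sign in _SIDE_SIGN.items():
        s = side.upper()
        sx = sign * body.shoulder_halfwidth
        sy = r["spine_shoulder"] * h
        p[JointId[f"SHOULDER_{s}"]] = (sx, sy, z0)
        p[JointId[f"ELBOW_{s}"]] = (sx, sy - body.upper_arm, z0)
        wy = sy - body.upper_arm - body.forearm
        p[JointId[f"WRIST_{s}"]] = (sx, wy, z0)
        p[JointId[f"HAND_{s}"]] = (sx, wy - r["hand"] * h, z0)
        p[JointId[f"HAND_TIP_{s}"]] = (sx, wy - 2 * r["hand"] * h, z0)
        p[JointId[f"THUMB_{s}"]] = (sx - sign * 0.02 * h, wy - 0.02 * h, z0)

        hx = sign * r["hip_halfwidth"] * h
        p[JointId[f"HIP_{s}"]] = (hx, r["spine_base"] * h, z0)
        p[JointId[f"KNEE_{s}"]] = (hx, r["ankle_height"] * h + body.shank, z0)
        p[JointId[f"ANKLE_{s}"]] = (hx, r["ankle_height"] * h, z0)
        p[JointId[f"FOOT_{s}"]] = (hx, 0.0, z0)
    return p


def _make_stream(
    frames_xyz: list[np.ndarray], rate: float, noise_sd_m: float, seed: int
) -> FrameStream:
    arr = np.stack(frames_xyz)
    if noise_sd_m > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd_m, arr.shape)
    frames = [SkeletalFrame(j / rate, arr[j]) for j in range(arr.shape[0])]
    return FrameStream(frames, nominal_rate=rate)


def _rep_profile(n: int) -> np.ndarray:
    """Smooth 0→1→0 activation over ``n`` frames, hitting 1 exactly mid-rep."""
    j = np.arange(n)
    return np.sin(math.pi * j / n) ** 2


def _tilt_upper_body(p: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Lean the torso (and everything attached to it) laterally by
    ``tilt_deg`` about the depth axis through SPINE_BASE."""
    if tilt_deg == 0.0:
        return p
    out = p.copy()
    theta = math.radians(tilt_deg)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta), 0.0],
         [math.sin(theta), math.cos(theta), 0.0],
         [0.0, 0.0, 1.0]]
    )
    pivot = p[JointId.SPINE_BASE]
    for j in _UPPER_BODY:
        out[j] = pivot + rot @ (p[j] - pivot)
    return out


def _pose_abduction(body, rest: np.ndarray, angle_deg: float, side: Side) -> np.ndarray:
    """Straight-arm lateral raise: the whole arm chain rotated ``angle_deg``
    from the downward direction within the frontal (x–y) plane."""
    p = rest.copy()
    s = side.upper()
    sign = _SIDE_SIGN[side]
    shoulder = rest[JointId[f"SHOULDER_{s}"]]
    a = math.radians(angle_deg)
    d = np.array([sign * math.sin(a), -math.cos(a), 0.0])
    hand_len = ANTHROPOMETRIC_RATIOS["hand"] * body.height
    p[JointId[f"ELBOW_{s}"]] = shoulder + body.upper_arm * d
    wrist = shoulder + (body.upper_arm + body.forearm) * d
    p[JointId[f"WRIST_{s}"]] = wrist
    p[JointId[f"HAND_{s}"]] = wrist + hand_len * d
    p[JointId[f"HAND_TIP_{s}"]] = wrist + 2 * hand_len * d
    p[JointId[f"THUMB_{s}"]] = wrist + hand_len * d + np.array([-sign * 0.02 * body.height, 0, 0])
    return p


def _pose_squat(
    body, rest: np.ndarray, knee_angle_deg: float, advance_m: float
) -> np.ndarray:
    """Double-leg squat pose with the commanded knee angle and commanded
    anteroposterior knee advance beyond the foot joints.

    Ankles and feet stay fixed; the knee moves toward the sensor by
    ``advance_m``; the hip is placed so the interior knee angle equals the
    command exactly; the torso translates rigidly with the pelvis, staying
    vertical.
    """
    if advance_m >= body.shank:
        raise InputError("knee advance exceeds shank length")
    p = rest.copy()
    phi = math.radians(knee_angle_deg)
    hips = {}
    for side in ("left", "right"):
        s = side.upper()
        ankle = rest[JointId[f"ANKLE_{s}"]]
        knee = ankle + np.array(
            [0.0, math.sqrt(body.shank**2 - advance_m**2), -advance_m]
        )
        u = (ankle - knee) / body.shank
        # Rotate u by the knee angle in the sagittal (y–z) plane so the hip
        # lands up/behind the knee.
        v = np.array(
            [0.0,
             u[1] * math.cos(phi) + u[2] * math.sin(phi),
             -u[1] * math.sin(phi) + u[2] * math.cos(phi)]
        )
        hip = knee + body.thigh * v
        p[JointId[f"KNEE_{s}"]] = knee
        p[JointId[f"HIP_{s}"]] = hip
        hips[side] = hip
    base = 0.5 * (hips["left"] + hips["right"])
    offset = base - rest[JointId.SPINE_BASE]
    p[JointId.SPINE_BASE] = base
    for j in _UPPER_BODY:
        p[j] = rest[j] + offset
    return p


def simulate_exercise(
    body: BodyModel,
    template: str,
    *,
    peak_or_min_angle: float | None = None,
    n_reps: int = 3,
    rep_duration_s: float = 2.0,
    rate: float = DEFAULT_FRAME_RATE_HZ,
    noise_sd_m: float = 0.0,
    tilt_deg: float = 0.0,
    knee_advance_cm: float = 0.0,
    hold_s: float = 4.0,
    asymmetry_m: float = 0.0,
    ramp_asymmetry_m: float = 0.06,
    side: Side = "right",
    distance_m: float = DEFAULT_DISTANCE_M,
    lead_s: float = 0.5,
    gap_s: float = 0.3,
    seed: int = 0,
) -> FrameStream:
    """Generate a synthetic exercise stream. Deterministic given ``seed``.

    Templates: ``concentric_angle`` (shoulder abduction to
    ``peak_or_min_angle``), ``posture_constrained_squat`` (descend to knee
    angle ``peak_or_min_angle``, knees advancing ``knee_advance_cm`` beyond
    the feet at full depth), ``isometric_hold`` (scapular retraction held
    statically for ``hold_s`` seconds, ramp and release marked by a lateral
    asymmetry so the hold span is well defined), and ``rest`` (stationary
    standing pose, for calibration).  Commanded extrema are achieved exactly
    before noise.
    """
    rest = rest_pose(body, distance_m)
    frames: list[np.ndarray] = []
    n_lead = int(round(lead_s * rate))
    n_gap = int(round(gap_s * rate))

    if template == "rest":
        duration = max(lead_s, rep_duration_s)
        n = max(2, int(round(duration * rate)))
        frames = [rest.copy() for _ in range(n)]
        return _make_stream(frames, rate, noise_sd_m, seed)

    if template == "concentric_angle":
        if peak_or_min_angle is None or not 0.0 < peak_or_min_angle <= 180.0:
            raise InputError("peak angle must lie in (0, 180]")
        m = int(round(rep_duration_s * rate))
        m += m % 2  # even count puts the commanded peak exactly on a frame
        profile = _rep_profile(m)
        frames += [rest.copy() for _ in range(n_lead)]
        for _ in range(n_reps):
            for sfrac in profile:
                frames.append(_pose_abduction(body, rest, peak_or_min_angle * sfrac, side))
            frames += [rest.copy() for _ in range(n_gap)]
        if tilt_deg:
            frames = [_tilt_upper_body(f, tilt_deg) for f in frames]
        return _make_stream(frames, rate, noise_sd_m, seed)

    if template == "posture_constrained_squat":
        if peak_or_min_angle is None or not 0.0 < peak_or_min_angle < 180.0:
            raise InputError("minimum knee angle must lie in (0, 180)")
        advance_m = knee_advance_cm / 100.0
        if advance_m < 0:
            raise InputError("knee_advance_cm must be >= 0")
        m = int(round(rep_duration_s * rate))
        m += m % 2
        profile = _rep_profile(m)
        frames += [rest.copy() for _ in range(n_lead)]
        for _ in range(n_reps):
            for sfrac in profile:
                angle = 180.0 - (180.0 - peak_or_min_angle) * sfrac
                frames.append(_pose_squat(body, rest, angle, advance_m * sfrac))
            frames += [rest.copy() for _ in range(n_gap)]
        return _make_stream(frames, rate, noise_sd_m, seed)

    if template == "isometric_hold":
        return _simulate_retraction(
            body, rest, rate, hold_s, asymmetry_m, ramp_asymmetry_m,
            noise_sd_m, seed,
        )

    raise InputError(f"unknown template {template!r}")


def _retraction_pose(
    rest: np.ndarray, w: float, ys: float, z0: float,
    g: float, c: float, a: float,
) -> np.ndarray:
    """Shoulders pulled back and together: |RS| = w+g, |LS| = w+g−a,
    |shoulder x span| = 2(w−c).  Depth offsets realize the lengths."""
    p = rest.copy()
    rs, ls = w + g, w + g - a
    x = w - c
    # Realize each commanded shoulder–sternum length exactly: push the
    # shoulder back in depth, or pull it inward when shorter than the span.
    x_r, b_r = x, math.sqrt(max(rs**2 - x**2, 0.0))
    x_l = min(x, ls)
    b_l = math.sqrt(max(ls**2 - x_l**2, 0.0))
    for s, sign, xs, b in (("RIGHT", -1.0, x_r, b_r), ("LEFT", 1.0, x_l, b_l)):
        shoulder = np.array([sign * xs, ys, z0 + b])
        delta = shoulder - rest[JointId[f"SHOULDER_{s}"]]
        for j in ("SHOULDER", "ELBOW", "WRIST", "HAND", "HAND_TIP", "THUMB"):
            p[JointId[f"{j}_{s}"]] = rest[JointId[f"{j}_{s}"]] + delta
    return p


def _simulate_retraction(
    body: BodyModel, rest: np.ndarray, rate: float, hold_s: float,
    asymmetry_m: float, ramp_asymmetry_m: float, noise_sd_m: float, seed: int,
    ramp_s: float = 1.0, release_s: float = 1.0,
    pull_m: float = 0.03, squeeze_m: float = 0.02,
) -> FrameStream:
    if hold_s <= 0:
        raise InputError("hold_s must be > 0")
    w = body.shoulder_halfwidth
    ys = rest[JointId.SPINE_SHOULDER][1]
    z0 = rest[JointId.SPINE_SHOULDER][2]
    n_ramp = int(round(ramp_s * rate))
    n_hold = int(round(hold_s * rate)) + 1
    n_rel = int(round(release_s * rate))
    frames: list[np.ndarray] = []
    for j in range(n_ramp):  # monotone retraction, marked by asymmetry
        u = (j + 1) / n_ramp
        frames.append(
            _retraction_pose(rest, w, ys, z0, pull_m * u, squeeze_m * u,
                             ramp_asymmetry_m * u)
        )
    for _ in range(n_hold):  # the commanded static hold
        frames.append(
            _retraction_pose(rest, w, ys, z0, pull_m, squeeze_m, asymmetry_m)
        )
    for j in range(n_rel):  # release mirrors the ramp
        u = 1.0 - (j + 1) / n_rel
        frames.append(
            _retraction_pose(rest, w, ys, z0, pull_m * u, squeeze_m * u,
                             ramp_asymmetry_m * (1 - u))
        )
    return _make_stream(frames, rate, noise_sd_m, seed)


def simulate_swipe(
    body: BodyModel,
    side: Side = "right",
    cross: bool = True,
    y_drift: float = 0.0,
    *,
    rate: float = DEFAULT_FRAME_RATE_HZ,
    duration_s: float = 1.5,
    noise_sd_m: float = 0.0,
    distance_m: float = DEFAULT_DISTANCE_M,
    seed: int = 0,
) -> FrameStream:
    """Horizontal hand-swipe trajectory.

    The active hand starts in the valid position (half the user's height,
    lateral to its shoulder) and sweeps along x; ``cross`` controls whether
    it passes the SPINE_MID x-coordinate.  ``y_drift`` (meters) is applied
    linearly over the first half of the sweep, before any crossing, to
    exercise the abort path.
    """
    rest = rest_pose(body, distance_m)
    s = side.upper()
    sign = _SIDE_SIGN[side]
    uh = body.tracked_height
    y0 = 0.5 * uh  # feet at y = 0 in the rest pose
    spine_x = rest[JointId.SPINE_MID][0]
    x_start = spine_x + sign * (body.shoulder_halfwidth + 0.15)
    x_end = spine_x + (-sign * 0.15 if cross else sign * 0.02)
    n = max(2, int(round(duration_s * rate)))
    frames = []
    for j in range(n):
        u = j / (n - 1)
        p = rest.copy()
        x = x_start + (x_end - x_start) * u
        y = y0 - y_drift * min(1.0, u / 0.5)
        hand = np.array([x, y, distance_m - 0.25])
        p[JointId[f"HAND_{s}"]] = hand
        p[JointId[f"HAND_TIP_{s}"]] = hand + np.array([0.0, 0.0, -0.02])
        p[JointId[f"THUMB_{s}"]] = hand + np.array([-sign * 0.02, 0.0, 0.0])
        p[JointId[f"WRIST_{s}"]] = hand + np.array([0.0, 0.03, 0.02])
        frames.append(p)
    return _make_stream(frames, rate, noise_sd_m, seed)


# ---------------------------------------------------------------------------
# Study-table generator
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Generating model of the longitudinal study table.

    ``average_angle = baseline(age group) + subject effect +
    (session − 1) × improvement(age group) + noise``.  Baselines worsen and
    improvement steps grow with age; squat improvements are negative (the
    angle decreases as performance improves).  Defaults emulate a 57-person
    cohort aged 65–80 over 6 sessions with compact distributions.
    """

    participants_per_group: tuple[int, ...] = (23, 18, 16)
    age_groups: tuple[tuple[int, int], ...] = ((65, 69), (70, 74), (75, 80))
    sessions: int = 6
    baseline_by_group: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "shoulder_abduction": (118.0, 104.0, 90.0),
            "double_leg_squat": (120.0, 134.0, 148.0),
        }
    )
    improvement_by_group: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "shoulder_abduction": (1.5, 2.5, 3.5),
            "double_leg_squat": (-1.5, -2.5, -3.5),
        }
    )
    subject_sd: float = 2.0  # degrees, between-participant spread
    noise_sd: float = 1.0  # degrees, per-record measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sessions < 2:
            raise InputError("a study needs at least 2 sessions")
        if len(self.participants_per_group) != len(self.age_groups):
            raise InputError("participants_per_group must match age_groups")
        for exercise, steps in self.improvement_by_group.items():
            if exercise not in self.baseline_by_group:
                raise InputError(f"no baseline for exercise {exercise!r}")
            if "squat" in exercise and any(s > 0 for s in steps):
                raise InputError(
                    "squat improvements must be expressed as an angle decrease"
                )


def simulate_study(config: StudyConfig | None = None) -> list[SessionRecord]:
    """One record per participant × exercise × session, deterministic given
    ``config.seed``."""
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    records: list[SessionRecord] = []
    pid = 0
    for gi, ((lo, hi), n) in enumerate(zip(config.age_groups, config.participants_per_group)):
        for i in range(n):
            pid += 1
            age = int(rng.integers(lo, hi + 1))
            gender = "M" if i % 2 == 0 else "F"
            for exercise, baselines in config.baseline_by_group.items():
                subject = float(rng.normal(0.0, config.subject_sd)) if config.subject_sd else 0.0
                step = config.improvement_by_group[exercise][gi]
                for session in range(1, config.sessions + 1):
                    noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
                    angle = baselines[gi] + subject + step * (session - 1) + noise
                    records.append(
                        SessionRecord(
                            participant_id=f"P{pid:03d}",
                            age=age,
                            gender=gender,
                            exercise_id=exercise,
                            session_index=session,
                            average_angle=angle,
                        )
                    )
    return records
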