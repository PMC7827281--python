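"""Frame-by-frame exercise assessment.

Evaluates a skeletal stream against an exercise prescription: repetitions
are segmented by hysteresis on the controlled angle relative to its
calibrated resting value, the range-of-motion extremum of each repetition
is recorded to 5 decimal places, and posture rules (torso tilt, knee over
toe, scapular-retraction conditions) are checked at every frame with the
margins of the selected tolerance profile.

Every check is causal — it uses only frames up to the current one — so
truncating a stream never changes violations already reported.  Comparisons
against tolerance limits carry a 1e−9 absolute slack so a pose exactly at a
printed margin classifies as valid despite floating-point round-off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .calibration import BiometricProfile
from .catalog import ExerciseSpec, ToleranceProfile
from .errors import AggregationError, CaptureError, InputError
from .skeleton import (
    MAX_OUT_OF_RANGE_FRACTION,
    FrameStream,
    JointId,
    Side,
    arm_elevation,
    knee_flexion,
    side_joints,
    torso_tilt,
)

logger = logging.getLogger(__name__)

#: Hysteresis thresholds for repetition segmentation, degrees of excursion
#: from the calibrated resting angle: a repetition opens above REP_OPEN_DEG
#: and closes when the excursion returns below REP_CLOSE_DEG.
REP_OPEN_DEG: float = 10.0
REP_CLOSE_DEG: float = 5.0

#: Absolute slack for comparisons against tolerance limits.
NUMERIC_SLACK: float = 1e-9

#: Decimal places of the recorded achievement measures.
RECORD_DECIMALS: int = 5


def round_half_away(x: float, decimals: int = RECORD_DECIMALS) -> float:
    """Round with ties going away from zero (unlike banker's rounding)."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


class Violation(NamedTuple):
    """A posture rule broken during a repetition (first offending frame)."""

    rule: str
    timestamp: float
    side: str


@dataclass
class RepetitionResult:
    """Outcome of one repetition: achievement angle, goal flag, validity."""

    index: int
    measured_angle: float  # degrees, recorded to 5 decimal places
    goal_met: bool
    valid: bool
    violations: list[Violation] = field(default_factory=list)


@dataclass
class ConditionCheck:
    """Per-frame evaluation of the four scapular-retraction conditions."""

    timestamp: float
    right_shoulder_retracting: bool  # |RS_t| >= |RS_{t-k}|
    left_shoulder_retracting: bool  # |LS_t| >= |LS_{t-k}|
    shoulders_approaching: bool  # |RL_t| <= |RL_{t-k}|
    symmetric: bool  # abs(|RS_t| - |LS_t|) < epsilon

    @property
    def all_met(self) -> bool:
        return (
            self.right_shoulder_retracting
            and self.left_shoulder_retracting
            and self.shoulders_approaching
            and self.symmetric
        )

    def failed(self) -> list[str]:
        names = []
        if not self.right_shoulder_retracting:
            names.append("right_shoulder_retraction")
        if not self.left_shoulder_retracting:
            names.append("left_shoulder_retraction")
        if not self.shoulders_approaching:
            names.append("shoulder_approach")
        if not self.symmetric:
            names.append("symmetry")
        return names


@dataclass
class IsometricResult:
    """Outcome of an isometric hold: duration and per-frame condition trace."""

    hold_duration: float  # seconds, longest span with all conditions met
    conditions_trace: list[ConditionCheck]
    goal_met: bool


@dataclass
class SessionRecord:
    """Per participant × exercise × session average achievement angle —
    the study's unit of analysis."""

    participant_id: str
    age: int
    gender: str
    exercise_id: str
    session_index: int
    average_angle: float


# ---------------------------------------------------------------------------
# Repetition segmentation
# ---------------------------------------------------------------------------


def _segment_repetitions(excursion: np.ndarray) -> list[tuple[int, int]]:
    """Hysteresis segmentation of the excursion trace into (start, end)
    frame-index spans, end inclusive.  An excursion still open at the end of
    the stream is closed at the final frame (keeps truncation causal)."""
    spans: list[tuple[int, int]] = []
    open_at: int | None = None
    for i, e in enumerate(excursion):
        if open_at is None:
            if e > REP_OPEN_DEG:
                open_at = i
        elif e < REP_CLOSE_DEG:
            spans.append((open_at, i))
            open_at = None
    if open_at is not None:
        spans.append((open_at, len(excursion) - 1))
    return spans


def _check_capture(stream: FrameStream) -> None:
    frac = stream.out_of_range_fraction()
    if frac > MAX_OUT_OF_RANGE_FRACTION:
        raise CaptureError(
            f"{frac:.0%} of frames out of depth range "
            f"(limit {MAX_OUT_OF_RANGE_FRACTION:.0%})"
        )


# ---------------------------------------------------------------------------
# Concentric (angular range-of-motion) exercises
# ---------------------------------------------------------------------------


def assess_concentric(
    stream: FrameStream, profile: BiometricProfile, spec: ExerciseSpec
) -> list[RepetitionResult]:
    """Assess a concentric angular exercise (e.g. shoulder abduction).

    The controlled angle for shoulder-family exercises is the arm-vs-body
    elevation; for knee-family concentric movements the knee flexion angle.
    ``measured_angle`` is the maximum excursion from the calibrated resting
    angle within the repetition.  A repetition is valid iff the torso tilt
    stays within the tolerance limit at every frame; goal achievement
    requires validity and the target angle less the angular tolerance.
    """
    if spec.template != "concentric_angle":
        raise InputError(f"spec {spec.id!r} is not a concentric_angle exercise")
    if spec.side not in ("left", "right"):
        raise InputError("concentric assessment requires a single-sided spec")
    _check_capture(stream)
    side: Side = spec.side  # type: ignore[assignment]

    if spec.family == "shoulder":
        angles = np.array([arm_elevation(f, side) for f in stream])
        resting = profile.resting_angles.get(f"arm_elevation_{side}", 0.0)
        excursion = angles - resting
    else:  # knee-family concentric: flexion away from the standing angle
        angles = np.array([knee_flexion(f, side) for f in stream])
        resting = profile.resting_angles.get(f"knee_flexion_{side}", 180.0)
        excursion = resting - angles

    tilts = np.array([torso_tilt(f) for f in stream])
    limit = spec.tolerance.torso_tilt_limit_deg
    ts = stream.timestamps

    results: list[RepetitionResult] = []
    spans = _segment_repetitions(excursion)
    if not spans:
        logger.warning("no repetitions detected in stream for %s", spec.id)
    for idx, (i0, i1) in enumerate(spans, start=1):
        measured = round_half_away(float(excursion[i0 : i1 + 1].max()))
        violations: list[Violation] = []
        bad = np.nonzero(tilts[i0 : i1 + 1] > limit + NUMERIC_SLACK)[0]
        if bad.size:
            violations.append(Violation("torso_tilt", float(ts[i0 + bad[0]]), "torso"))
        valid = not violations
        goal_met = valid and (
            measured >= spec.target - spec.tolerance.angular_goal_tolerance_deg - NUMERIC_SLACK
        )
        results.append(RepetitionResult(idx, measured, goal_met, valid, violations))
        logger.info(
            "repetition %d: measured %.5f°, goal_met=%s, valid=%s",
            idx, measured, goal_met, valid,
        )
    return results


# ---------------------------------------------------------------------------
# Posture-constrained squat
# ---------------------------------------------------------------------------


def knee_advance_cm(frame, side: Side) -> float:
    """Anteroposterior advance of the knee beyond the foot joint, cm.

    The user faces the sensor, so forward = decreasing z; the advance is
    ``max(0, z_foot − z_knee)``.  The foot joint proxies the tip of the feet.
    """
    joints = side_joints(side)
    z_knee = frame.positions[joints["knee"]][2]
    z_foot = frame.positions[joints["foot"]][2]
    return max(0.0, (z_foot - z_knee)) * 100.0


def assess_squat(
    stream: FrameStream, profile: BiometricProfile, spec: ExerciseSpec
) -> list[RepetitionResult]:
    """Assess a double-leg squat.

    ``measured_angle`` is the worse (larger) of the two knees' minimum
    angles within the repetition — the correct range of motion runs from
    180° upright down to 90° with the thighs parallel to the floor, so lower
    is better.  A repetition is valid iff neither knee advances beyond its
    foot joint by more than the tolerance limit at any frame.
    """
    if spec.template != "posture_constrained_squat":
        raise InputError(f"spec {spec.id!r} is not a posture_constrained_squat")
    _check_capture(stream)

    left = np.array([knee_flexion(f, "left") for f in stream])
    right = np.array([knee_flexion(f, "right") for f in stream])
    resting = min(
        profile.resting_angles.get("knee_flexion_left", 180.0),
        profile.resting_angles.get("knee_flexion_right", 180.0),
    )
    excursion = resting - np.minimum(left, right)

    adv = {
        s: np.array([knee_advance_cm(f, s) for f in stream]) for s in ("left", "right")
    }
    limit = spec.tolerance.knee_deviation_limit_cm
    ts = stream.timestamps

    results: list[RepetitionResult] = []
    spans = _segment_repetitions(excursion)
    if not spans:
        logger.warning("no repetitions detected in stream for %s", spec.id)
    for idx, (i0, i1) in enumerate(spans, start=1):
        deepest = max(float(left[i0 : i1 + 1].min()), float(right[i0 : i1 + 1].min()))
        measured = round_half_away(deepest)
        violations: list[Violation] = []
        first_bad: tuple[float, str] | None = None
        for s in ("left", "right"):
            bad = np.nonzero(adv[s][i0 : i1 + 1] > limit + NUMERIC_SLACK * 100)[0]
            if bad.size:
                t_bad = float(ts[i0 + bad[0]])
                if first_bad is None or t_bad < first_bad[0]:
                    first_bad = (t_bad, s)
        if first_bad is not None:
            violations.append(Violation("knee_over_toe", first_bad[0], first_bad[1]))
        valid = not violations
        goal_met = valid and (
            measured <= spec.target + spec.tolerance.angular_goal_tolerance_deg + NUMERIC_SLACK
        )
        results.append(RepetitionResult(idx, measured, goal_met, valid, violations))
        logger.info(
            "repetition %d: measured %.5f°, goal_met=%s, valid=%s",
            idx, measured, goal_met, valid,
        )
    return results


# ---------------------------------------------------------------------------
# Isometric scapular retraction
# ---------------------------------------------------------------------------


def assess_isometric_retraction(
    stream: FrameStream, tolerance: ToleranceProfile, hold_target: float
) -> IsometricResult:
    """Assess an isometric scapular-retraction hold.

    With R = SHOULDER_RIGHT, S = SPINE_SHOULDER, L = SHOULDER_LEFT, at every
    frame t ≥ k four conditions are evaluated against frame t−k:
    |RS_t| ≥ |RS_{t−k}|, |LS_t| ≥ |LS_{t−k}|, |RL_t| ≤ |RL_{t−k}| and
    abs(|RS_t| − |LS_t|) < ε — the shoulders approach each other, both
    moving away from the sternum, symmetrically.  ``hold_duration`` is the
    longest contiguous span where all four hold; the trace identifies which
    condition (and which shoulder) failed otherwise.
    """
    k = tolerance.retraction_k_frames
    eps = tolerance.retraction_epsilon_m
    n = len(stream)
    if n <= k:
        raise InputError(f"stream of {n} frames too short for k = {k}")

    pos = stream.as_array()
    rs = np.linalg.norm(
        pos[:, JointId.SPINE_SHOULDER] - pos[:, JointId.SHOULDER_RIGHT], axis=1
    )
    ls = np.linalg.norm(
        pos[:, JointId.SPINE_SHOULDER] - pos[:, JointId.SHOULDER_LEFT], axis=1
    )
    rl = np.linalg.norm(
        pos[:, JointId.SHOULDER_LEFT] - pos[:, JointId.SHOULDER_RIGHT], axis=1
    )
    ts = stream.timestamps

    trace: list[ConditionCheck] = []
    for t in range(k, n):
        trace.append(
            ConditionCheck(
                timestamp=float(ts[t]),
                right_shoulder_retracting=bool(rs[t] >= rs[t - k] - NUMERIC_SLACK),
                left_shoulder_retracting=bool(ls[t] >= ls[t - k] - NUMERIC_SLACK),
                shoulders_approaching=bool(rl[t] <= rl[t - k] + NUMERIC_SLACK),
                symmetric=bool(abs(rs[t] - ls[t]) < eps),
            )
        )

    # Longest contiguous all-met span, in seconds (m frames → (m−1)/rate).
    best = run = 0
    for check in trace:
        run = run + 1 if check.all_met else 0
        best = max(best, run)
    hold = (best - 1) / stream.nominal_rate if best >= 1 else 0.0
    goal_met = hold >= hold_target - NUMERIC_SLACK
    logger.info("isometric hold %.3f s (target %.3f s): goal_met=%s",
                hold, hold_target, goal_met)
    return IsometricResult(hold, trace, goal_met)


# ---------------------------------------------------------------------------
# Session scoring
# ---------------------------------------------------------------------------


def score_session(
    results: "Sequence[RepetitionResult] | Sequence[IsometricResult]",
    spec: ExerciseSpec,
) -> tuple[float, float]:
    """Session aggregate: (average achievement, score in points).

    The average of the per-repetition achievement measure (angle, or hold
    duration for isometric exercises) is the session performance measure,
    recorded to 5 decimals.  The score is 100 × the mean achievement ratio
    clipped to [0, 1]: concentric measured/target, squat
    (180−measured)/(180−target), isometric hold/target.
    """
    if not results:
        raise AggregationError("cannot aggregate an empty result set")
    if isinstance(results[0], IsometricResult):
        values = [r.hold_duration for r in results]  # type: ignore[union-attr]
        ratios = [v / spec.target for v in values]
    else:
        values = [r.measured_angle for r in results]  # type: ignore[union-attr]
        if spec.template == "posture_constrained_squat":
            ratios = [(180.0 - v) / (180.0 - spec.target) for v in values]
        else:
            ratios = [v / spec.target for v in values]
    average = round_half_away(float(np.mean(values)))
    score = 100.0 * float(np.mean(np.clip(ratios, 0.0, 1.0)))
    return average, score
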