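"""Exercise assessment: segmentation, validity rules, ROM measurement, scoring."""

import numpy as np
import pytest

from gerofit.assessment import (
    assess_concentric,
    assess_isometric_retraction,
    assess_squat,
    round_half_away,
    score_session,
)
from gerofit.catalog import ELDERLY, STRICT, find_exercise
from gerofit.errors import AggregationError, InputError
from gerofit.simulator import simulate_exercise
from gerofit.skeleton import FrameStream, JointId, SkeletalFrame


def _with_tolerance(spec, tolerance):
    return spec.model_copy(update={"tolerance": tolerance})


@pytest.fixture(scope="module")
def abduction_spec(catalog):
    return find_exercise(catalog, "shoulder_abduction_right_90")


@pytest.fixture(scope="module")
def squat_spec(catalog):
    return find_exercise(catalog, "double_leg_squat_110")


def _elevation_oracle(stream):
    """Per-frame arm-vs-body angle recomputed from raw coordinates."""
    pos = stream.as_array()
    arm = pos[:, JointId.WRIST_RIGHT] - pos[:, JointId.SHOULDER_RIGHT]
    down = pos[:, JointId.SPINE_BASE] - pos[:, JointId.SPINE_SHOULDER]
    cos = (arm * down).sum(1) / (
        np.linalg.norm(arm, axis=1) * np.linalg.norm(down, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cos, -1, 1)))


class TestConcentric:
    def test_commanded_peak_measured_exactly(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=1
        )
        reps = assess_concentric(stream, profile, abduction_spec)
        assert len(reps) == 1
        r = reps[0]
        assert r.measured_angle == pytest.approx(95.0, abs=1e-5)
        assert r.goal_met and r.valid and not r.violations
        # independent oracle: the commanded peak is the max per-frame angle
        assert r.measured_angle == pytest.approx(
            float(_elevation_oracle(stream).max()), abs=1e-5
        )

    def test_excess_tilt_invalidates_repetition(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=1, tilt_deg=25.0
        )
        reps = assess_concentric(
            stream, profile, _with_tolerance(abduction_spec, ELDERLY)
        )
        assert len(reps) == 1
        assert not reps[0].valid and not reps[0].goal_met
        assert reps[0].violations[0].rule == "torso_tilt"

    def test_tilt_at_the_margin_is_valid(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=1, tilt_deg=20.0
        )
        reps = assess_concentric(
            stream, profile, _with_tolerance(abduction_spec, ELDERLY)
        )
        assert reps[0].valid

    def test_static_stream_has_no_repetitions(self, body, profile, abduction_spec):
        stream = simulate_exercise(body, "rest", lead_s=2.0)
        assert assess_concentric(stream, profile, abduction_spec) == []

    def test_multiple_reps_segmented(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=4
        )
        reps = assess_concentric(stream, profile, abduction_spec)
        assert [r.index for r in reps] == [1, 2, 3, 4]

    def test_goal_tolerance_applied_one_sided(self, body, profile, abduction_spec):
        # target 90, elderly tolerance 5: an 86° peak still meets the goal.
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=86.0, n_reps=1
        )
        reps = assess_concentric(
            stream, profile, _with_tolerance(abduction_spec, ELDERLY)
        )
        assert reps[0].goal_met
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=84.0, n_reps=1
        )
        reps = assess_concentric(
            stream, profile, _with_tolerance(abduction_spec, ELDERLY)
        )
        assert not reps[0].goal_met

    def test_jittered_measurement_within_2_degrees(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=1,
            noise_sd_m=0.005, seed=42,
        )
        reps = assess_concentric(stream, profile, abduction_spec)
        assert len(reps) >= 1
        assert reps[0].measured_angle == pytest.approx(95.0, abs=2.0)


class TestSquat:
    def test_commanded_depth_measured_exactly(self, body, profile, squat_spec):
        stream = simulate_exercise(
            body, "posture_constrained_squat", peak_or_min_angle=100.0, n_reps=1
        )
        reps = assess_squat(stream, profile, _with_tolerance(squat_spec, STRICT))
        assert len(reps) == 1
        r = reps[0]
        assert r.measured_angle == pytest.approx(100.0, abs=1e-5)
        assert r.valid and r.goal_met

    def test_knee_beyond_margin_invalidates(self, body, profile, squat_spec):
        stream = simulate_exercise(
            body, "posture_constrained_squat", peak_or_min_angle=100.0, n_reps=1,
            knee_advance_cm=11.0,
        )
        reps = assess_squat(stream, profile, _with_tolerance(squat_spec, ELDERLY))
        assert not reps[0].valid
        v = reps[0].violations[0]
        assert v.rule == "knee_over_toe" and v.side in ("left", "right")

    def test_advance_at_the_margin_is_valid(self, body, profile, squat_spec):
        stream = simulate_exercise(
            body, "posture_constrained_squat", peak_or_min_angle=100.0, n_reps=1,
            knee_advance_cm=10.0,
        )
        reps = assess_squat(stream, profile, _with_tolerance(squat_spec, ELDERLY))
        assert reps[0].valid

    def test_upright_stream_no_reps_and_180_knee(self, body, profile, squat_spec, rest_stream):
        from gerofit.skeleton import knee_flexion

        assert assess_squat(rest_stream, profile, squat_spec) == []
        assert knee_flexion(rest_stream[0], "left") == pytest.approx(180.0, abs=1e-9)

    def test_strict_valid_implies_elderly_valid(self, body, profile, squat_spec):
        # Tolerance monotonicity across the nested margin profiles.
        for adv in (0.0, 5.0, 10.0, 15.0):
            stream = simulate_exercise(
                body, "posture_constrained_squat", peak_or_min_angle=100.0,
                n_reps=1, knee_advance_cm=adv,
            )
            strict_ok = all(
                r.valid
                for r in assess_squat(stream, profile, _with_tolerance(squat_spec, STRICT))
            )
            elderly_ok = all(
                r.valid
                for r in assess_squat(stream, profile, _with_tolerance(squat_spec, ELDERLY))
            )
            assert elderly_ok or not strict_ok


class TestIsometricRetraction:
    def test_static_pose_holds_throughout(self, body):
        stream = simulate_exercise(body, "rest", lead_s=3.0)
        res = assess_isometric_retraction(stream, ELDERLY, hold_target=1.0)
        assert all(c.all_met for c in res.conditions_trace)
        expected = stream.duration - ELDERLY.retraction_k_frames / stream.nominal_rate
        assert res.hold_duration == pytest.approx(expected, abs=1e-9)

    def test_commanded_hold_recovered(self, body):
        stream = simulate_exercise(body, "isometric_hold", hold_s=4.0)
        res = assess_isometric_retraction(stream, ELDERLY, hold_target=4.0)
        assert res.hold_duration == pytest.approx(4.0, abs=1 / stream.nominal_rate)
        assert res.goal_met

    def test_asymmetric_execution_blamed_on_symmetry(self, body):
        eps = ELDERLY.retraction_epsilon_m
        stream = simulate_exercise(
            body, "isometric_hold", hold_s=4.0, asymmetry_m=2 * eps
        )
        res = assess_isometric_retraction(stream, ELDERLY, hold_target=4.0)
        assert res.hold_duration == 0.0 and not res.goal_met
        failed = [c.failed() for c in res.conditions_trace if not c.all_met]
        assert any("symmetry" in f for f in failed)

    def test_too_short_stream_rejected(self, body, rest_positions):
        frames = [SkeletalFrame(j / 30, rest_positions) for j in range(5)]
        with pytest.raises(InputError):
            assess_isometric_retraction(FrameStream(frames), ELDERLY, 1.0)

    def test_hold_independent_of_k_on_bounded_hold(self, body):
        # Smaller k makes the rules more local, never lengthening the hold.
        stream = simulate_exercise(body, "isometric_hold", hold_s=3.0)
        holds = []
        for k in (15, 10, 5):
            tol = ELDERLY.model_copy(update={"retraction_k_frames": k})
            holds.append(
                assess_isometric_retraction(stream, tol, 3.0).hold_duration
            )
        assert holds[0] >= holds[1] >= holds[2]


class TestCausality:
    def test_truncation_preserves_reported_violations(self, body, profile, abduction_spec):
        stream = simulate_exercise(
            body, "concentric_angle", peak_or_min_angle=95.0, n_reps=2, tilt_deg=25.0
        )
        spec = _with_tolerance(abduction_spec, ELDERLY)
        full = assess_concentric(stream, profile, spec)
        cut = len(stream) * 2 // 3
        t_cut = stream[cut - 1].timestamp
        truncated = FrameStream(stream.frames[:cut], stream.nominal_rate)
        part = assess_concentric(truncated, profile, spec)
        full_v = [v for r in full for v in r.violations if v.timestamp <= t_cut]
        part_v = [v for r in part for v in r.violations if v.timestamp <= t_cut]
        assert part_v == full_v


class TestScoring:
    def test_average_is_arithmetic_mean(self, abduction_spec):
        from gerofit.assessment import RepetitionResult

        reps = [RepetitionResult(i, a, True, True) for i, a in enumerate([90, 100, 110])]
        average, _ = score_session(reps, abduction_spec)
        assert average == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize(
        "angles,expected",
        [([100.0, 100.0], 100.0), ([50.0, 100.0], 75.0), ([150.0, 100.0], 100.0)],
    )
    def test_clipped_ratio_score(self, catalog, angles, expected):
        from gerofit.assessment import RepetitionResult

        spec = find_exercise(catalog, "shoulder_abduction_right_90").model_copy(
            update={"target": 100.0}
        )
        reps = [RepetitionResult(i, a, True, True) for i, a in enumerate(angles)]
        _, score = score_session(reps, spec)
        assert score == pytest.approx(expected, abs=1e-9)

    def test_squat_score_uses_inverted_scale(self, squat_spec):
        from gerofit.assessment import RepetitionResult

        # target 110: measured 110 is full achievement, 145 is half.
        reps = [RepetitionResult(1, 145.0, False, True)]
        _, score = score_session(reps, squat_spec)
        assert score == pytest.approx(50.0, abs=1e-9)

    def test_empty_results_rejected(self, abduction_spec):
        with pytest.raises(AggregationError):
            score_session([], abduction_spec)

    def test_rounding_half_away_from_zero(self):
        # ties at the .5 boundary go away from zero, not to the even digit
        assert round_half_away(2.5, 0) == 3.0
        assert round_half_away(-2.5, 0) == -3.0
        assert round_half_away(1.5, 0) == 2.0
        assert round_half_away(95.123456789, 5) == 95.12346
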