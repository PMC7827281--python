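"""Rule-based finite-state recognizer for the horizontal hand swipe.

The swipe advances the interaction flow without any physical controller: a
hand validates the starting position when it sits at half the user's height
and away from the trunk, tracks while it moves along x with its height
approximately constant, and completes the gesture at the first frame where
it crosses the x-coordinate of SPINE_MID toward the contralateral side.
Leaving the height band before crossing aborts the episode; the recognizer
returns to idle and may re-arm.

Palm orientation cannot be inferred from joint positions alone and is not
checked (documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .errors import InputError
from .skeleton import FrameStream, JointId

logger = logging.getLogger(__name__)

#: Half-width of the valid-height band as a fraction of user height.
Y_BAND_FRACTION: float = 0.1

#: Travel toward the spine (m) after arming before the episode counts as
#: actively tracking.
TRACK_MIN_TRAVEL_M: float = 0.02

#: A hand must sit at least this far (m) beyond its own shoulder's lateral
#: offset to count as "away from the trunk" — a hand hanging at rest lies
#: exactly at shoulder offset and must not arm the recognizer.
TRUNK_CLEARANCE_MARGIN_M: float = 0.05


class Phase(str, Enum):
    IDLE = "IDLE"
    ARMED = "ARMED"
    TRACKING = "TRACKING"
    COMPLETED = "COMPLETED"
    ABORTED = "ABORTED"


@dataclass
class GestureState:
    """One recognizer transition: the phase entered, by which hand, when."""

    state: Phase
    active_hand: str  # "left" | "right" | "none"
    entered_at: float


_HANDS = {
    "left": (JointId.HAND_LEFT, JointId.SHOULDER_LEFT),
    "right": (JointId.HAND_RIGHT, JointId.SHOULDER_RIGHT),
}


def recognize_swipe(
    stream: FrameStream, user_height: float
) -> tuple[bool, float | None, list[GestureState]]:
    """Scan a stream for a completed horizontal swipe.

    Returns ``(completed, completion_time, trace)``.  The completion time is
    the timestamp of the first frame where the active hand's x crosses the
    SPINE_MID x toward the contralateral side; recognition is causal, so any
    extension of a completing stream reports the same completion time.
    """
    if len(stream) == 0:
        raise InputError("empty stream")
    if user_height <= 0:
        raise InputError(f"user_height must be > 0, got {user_height}")

    band = Y_BAND_FRACTION * user_height
    trace: list[GestureState] = [GestureState(Phase.IDLE, "none", stream[0].timestamp)]
    phase = Phase.IDLE
    hand_name = "none"
    armed_offset = 0.0

    for frame in stream:
        spine_x = frame.positions[JointId.SPINE_MID][0]
        foot_y = min(
            frame.positions[JointId.FOOT_LEFT][1],
            frame.positions[JointId.FOOT_RIGHT][1],
        )
        y_center = foot_y + 0.5 * user_height

        def in_band(hand_joint: JointId) -> bool:
            return abs(frame.positions[hand_joint][1] - y_center) <= band

        if phase in (Phase.IDLE, Phase.ABORTED):
            # Look for a hand in a valid starting position: inside the height
            # band and lateral to its own shoulder ("away from the trunk").
            best: tuple[float, str] | None = None
            for name, (hand_j, shoulder_j) in _HANDS.items():
                sign = 1.0 if frame.positions[shoulder_j][0] >= spine_x else -1.0
                offset = (frame.positions[hand_j][0] - spine_x) * sign
                clearance = abs(frame.positions[shoulder_j][0] - spine_x)
                if in_band(hand_j) and offset >= clearance + TRUNK_CLEARANCE_MARGIN_M:
                    if best is None or offset > best[0]:
                        best = (offset, name)
            if best is not None:
                phase, hand_name, armed_offset = Phase.ARMED, best[1], best[0]
                trace.append(GestureState(phase, hand_name, frame.timestamp))
            continue

        # ARMED or TRACKING: follow the active hand.
        hand_j, shoulder_j = _HANDS[hand_name]
        sign = 1.0 if frame.positions[shoulder_j][0] >= spine_x else -1.0
        offset = (frame.positions[hand_j][0] - spine_x) * sign

        if not in_band(hand_j):
            phase, hand_name = Phase.ABORTED, "none"
            trace.append(GestureState(phase, hand_name, frame.timestamp))
            logger.info("swipe aborted at t=%.3f (left the height band)", frame.timestamp)
            continue
        if offset < 0.0:  # crossed SPINE_MID toward the contralateral side
            trace.append(GestureState(Phase.COMPLETED, hand_name, frame.timestamp))
            logger.info("swipe completed at t=%.3f by %s hand", frame.timestamp, hand_name)
            return True, frame.timestamp, trace
        if phase is Phase.ARMED and armed_offset - offset >= TRACK_MIN_TRAVEL_M:
            phase = Phase.TRACKING
            trace.append(GestureState(phase, hand_name, frame.timestamp))

    return False, None, trace
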