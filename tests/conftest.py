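import numpy as np
import pytest

from gerofit.calibration import calibrate
from gerofit.catalog import default_catalog
from gerofit.simulator import BodyModel, rest_pose, simulate_exercise
from gerofit.skeleton import FrameStream, SkeletalFrame


@pytest.fixture(scope="session")
def body():
    return BodyModel.from_height(1.65)


@pytest.fixture(scope="session")
def rest_positions(body):
    return rest_pose(body)


@pytest.fixture(scope="session")
def rest_stream(body):
    return simulate_exercise(body, "rest", lead_s=1.0)


@pytest.fixture(scope="session")
def profile(body, rest_stream):
    return calibrate(rest_stream, "right", user_id="TEST")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def make_frame(rest_positions):
    """Frame factory: the standing rest pose with selected joints overridden."""

    def _make(timestamp=0.0, **overrides):
        p = rest_positions.copy()
        for joint, xyz in overrides.items():
            p[getattr(__import__("gerofit").JointId, joint)] = xyz
        return SkeletalFrame(timestamp, p)

    return _make


def static_stream(frame: SkeletalFrame, n: int, rate: float = 30.0) -> FrameStream:
    """A stream repeating one pose (timestamps regenerated at the rate)."""
    frames = [SkeletalFrame(j / rate, frame.positions.copy()) for j in range(n)]
    return FrameStream(frames, nominal_rate=rate)


def jittered(stream: FrameStream, sd_m: float, seed: int) -> FrameStream:
    rng = np.random.default_rng(seed)
    frames = [
        SkeletalFrame(f.timestamp, f.positions + rng.normal(0, sd_m, (25, 3)))
        for f in stream
    ]
    return FrameStream(frames, nominal_rate=stream.nominal_rate)
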