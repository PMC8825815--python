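import pytest

from ergopose.kinematics import ANGLE_JOINTS, JointAngleFrame
from ergopose.synthgen import generate_sequence, squat_preset


def make_angle_frame(frame_index=0, side="right", hip_drop_ratio=0.95, valid=None, **flexions):
    """A JointAngleFrame with the given flexion angles, 0 deg elsewhere."""
    angles = {j: 0.0 for j in ANGLE_JOINTS}
    angles.update(flexions)
    validity = {j: True for j in ANGLE_JOINTS}
    if valid is not None:
        validity.update(valid)
    return JointAngleFrame(
        frame_index=frame_index, side=side, angles=angles, valid=validity,
        hip_drop_ratio=hip_drop_ratio,
    )


@pytest.fixture
def angle_frame_factory():
    return make_angle_frame


@pytest.fixture
def neutral_frame():
    return make_angle_frame()


@pytest.fixture(scope="session")
def squat_sequence():
    """Noise-free squat cycle: 10 s at 30 fps = 300 frames."""
    return generate_sequence(squat_preset())
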