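import numpy as np
import pytest

from hyokin.landmark_io import (
    Consistency,
    LandmarkFrame,
    StimulusLevel,
    SwallowRecording,
    Thickener,
)

C4 = np.array([100.0, 200.0])
C2 = np.array([100.0, 140.0])  # vertical spine, scalar 60 px, patient faces right


def frame_at_xy(frame_index: int, xy: float, present: bool = True) -> LandmarkFrame:
    """Frame whose hyoid sits on the anterior axis at the given XY %(C2-4).

    With the hyoid on the x-axis, X == XY and Y == 0, so kinematics tests
    can specify XY histories directly.
    """
    hyoid = C4 + np.array([xy / 100.0 * 60.0, 0.0]) if present else None
    return LandmarkFrame(frame_index=frame_index, c2=C2.copy(), c4=C4.copy(), hyoid=hyoid)


def recording_from_xy(
    xy_values,
    *,
    present=None,
    recording_id="R1",
    participant_id="P01",
    annotated_burst_frame=None,
    frame_rate_hz=30.0,
) -> SwallowRecording:
    present = [True] * len(xy_values) if present is None else present
    frames = [
        frame_at_xy(i, xy, ok) for i, (xy, ok) in enumerate(zip(xy_values, present))
    ]
    return SwallowRecording(
        recording_id=recording_id,
        participant_id=participant_id,
        stimulus=StimulusLevel(Consistency.TN0, Thickener.NONE),
        repetition=1,
        sip_volume_ml=15.0,
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        annotated_burst_frame=annotated_burst_frame,
    )


@pytest.fixture
def xy_recording():
    return recording_from_xy
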