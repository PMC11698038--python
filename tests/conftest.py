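import numpy as np
import pytest
from hypothesis import settings

from springboard.tracking_io import JumpRecording, Morphometrics, TrackedSeries

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def control_morph() -> Morphometrics:
    """Morphometrics at the study-population control means."""
    return Morphometrics(
        animal_id="gh01",
        body_mass=1.13e-3,
        tibia_length=15.6e-3,
        takeoff_angle_deg=113.0,
    )


def make_recording(
    p0=(0.0, 0.0),
    p1=(0.0102, 0.0102),
    *,
    tarsus=None,
    fixed_end=(0.0, 0.0),
    first_movement=0,
    last_contact=28,
    frame_rate=1000.0,
    platform_id="control",
    line_index=None,
) -> JumpRecording:
    """Recording with the body landmark at p0 (last contact) and p1 (+10 ms)."""
    n_window = int(round(0.010 * frame_rate))
    pos = {first_movement: p0, last_contact: p0, last_contact + n_window: p1}
    frames = np.array(sorted(pos))
    body = TrackedSeries(
        frame_index=frames,
        time=frames / frame_rate,
        x=np.array([pos[f][0] for f in frames]),
        y=np.array([pos[f][1] for f in frames]),
        calibrated=True,
    )
    tarsus_series = None
    if tarsus is not None:
        (t0, t1) = tarsus
        tframes = np.array([first_movement, last_contact])
        tarsus_series = TrackedSeries(
            frame_index=tframes,
            time=tframes / frame_rate,
            x=np.array([t0[0], t1[0]]),
            y=np.array([t0[1], t1[1]]),
            calibrated=True,
        )
    return JumpRecording(
        body_series=body,
        tarsus_series=tarsus_series,
        frame_rate=frame_rate,
        scale=1.0,
        animal_id="gh01",
        platform_id=platform_id,
        line_index=line_index,
        first_movement_frame=first_movement,
        last_contact_frame=last_contact,
        fixed_end_xy=fixed_end,
    )
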