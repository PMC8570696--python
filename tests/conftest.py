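import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from foragekit.track_io import StateCode, TrackRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STATE_LETTERS = {
    "F": StateCode.FORWARD.value,
    "R": StateCode.REVERSAL.value,
    "O": StateCode.OMEGA_TURN.value,
    "S": StateCode.SHALLOW_TURN.value,
    "P": StateCode.PAUSE.value,
    "X": StateCode.OTHER.value,
}


def build_track(
    states,
    frame_rate_hz=3.0,
    speeds=None,
    x=None,
    y=None,
    track_id="t0",
    plate_id="p0",
    condition="test",
    worm_length_mm=1.0,
    t0_offset_s=0.0,
    **kwargs,
):
    """Construct a TrackRecord from a compact state string like "FFRRRF"."""
    if isinstance(states, str):
        states = [STATE_LETTERS[c] for c in states]
    n = len(states)
    dt = 1.0 / frame_rate_hz
    if speeds is None:
        speeds = np.full(n, 0.15)
    if x is None:
        x = np.cumsum(np.asarray(speeds, float) * dt) - speeds[0] * dt
    if y is None:
        y = np.zeros(n)
    frames = pd.DataFrame(
        {
            "time_s": t0_offset_s + np.arange(n) * dt,
            "x_mm": np.asarray(x, float),
            "y_mm": np.asarray(y, float),
            "state": states,
            "speed_mm_s": np.asarray(speeds, float),
        }
    )
    return TrackRecord(
        track_id=track_id,
        plate_id=plate_id,
        condition=condition,
        t0_offset_s=t0_offset_s,
        frame_rate_hz=frame_rate_hz,
        frames=frames,
        worm_length_mm=worm_length_mm,
        pixel_size_mm=0.05,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))
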