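import numpy as np
import pytest

from hyphatrack.trajectory_io import Detection, Trajectory, TrackSet


def make_track(track_id, coords, t0=0.0, dt=0.024, frame0=0):
    """Build a trajectory from (x, y) pairs at consecutive frames."""
    return Trajectory(track_id, [
        Detection(frame0 + i, float(x), float(y), t0 + i * dt)
        for i, (x, y) in enumerate(coords)
    ])


def constant_speed_track(track_id, speed, n_frames, dt=0.024):
    """A straight-line runner along x at a constant speed (µm/s)."""
    return make_track(track_id, [(speed * dt * i, 0.0) for i in range(n_frames)], dt=dt)


@pytest.fixture
def simple_trackset():
    return TrackSet([
        make_track("A", [(0, 0), (3 * 0.024, 4 * 0.024)]),
        constant_speed_track("B", 20.0, 30),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
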