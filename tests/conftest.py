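import numpy as np
import pytest

from macromigr import simkit
from macromigr.core import Calibration, Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_track():
    """Collinear track: 4 points 1 µm apart, 10 min/frame."""
    return Track(0, frames=[0, 1, 2, 3], x=[0, 1, 2, 3], y=[0, 0, 0, 0])


@pytest.fixture
def lam_truth():
    """Small laminin-like simulation with slingshots."""
    params = simkit.SimParams(
        n_cells=20, n_frames=60, seed=7, mode=simkit.LAM_LIKE,
        field_size=(2048, 2048),
    )
    return simkit.simulate_tracks(params), params


def random_tracks(rng, n, cal=None, max_frames=60):
    """Random synthetic tracks with varied duration/speed/displacement."""
    cal = cal or Calibration()
    tracks = []
    for i in range(n):
        length = int(rng.integers(2, max_frames))
        start = int(rng.integers(0, 5))
        frames = start + np.arange(length)
        scale = rng.uniform(0.1, 6.0)
        x = np.cumsum(rng.normal(0, scale, length)) + rng.uniform(0, 500)
        y = np.cumsum(rng.normal(0, scale, length)) + rng.uniform(0, 500)
        tracks.append(Track(i, frames, x, y, cal))
    return tracks
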