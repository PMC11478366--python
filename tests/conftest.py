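"""Shared fixtures: small hand-built tracks and deterministic generators."""

import numpy as np
import pytest

from pointfall.core import PointCloudFrame, SubjectTrack


def make_spot_track(spot_positions, labels=None, frame_rate=10.0, points_per_frame=6,
                    scenario="walk", seed=0):
    """A minimal track whose spot follows the given positions exactly.

    Each frame also gets a small deterministic point cloud so feature code
    has something to chew on.
    """
    rng = np.random.default_rng(seed)
    spot_positions = np.asarray(spot_positions, dtype=float)
    n = len(spot_positions)
    frames = []
    for i, pos in enumerate(spot_positions):
        pts = pos + rng.normal(0.0, 0.1, (points_per_frame, 3))
        frames.append(PointCloudFrame(i, i / frame_rate, pts, [(0, pos)]))
    labels = np.ones(n, dtype=int) if labels is None else np.asarray(labels)
    return SubjectTrack(
        subject_id="fixture",
        scenario=scenario,
        frames=frames,
        labels=labels,
        frame_rate=frame_rate,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_track():
    pos = np.tile([2.0, 2.0, 1.1], (30, 1))
    return make_spot_track(pos)
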