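"""Domain types and track serialization round-trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pointfall.core import (
    GroundTruth,
    PointCloudFrame,
    PostureLabel,
    SchemaError,
    SubjectTrack,
)
from pointfall.io import read_track, write_track


def test_posture_label_codes():
    assert PostureLabel(1).name == "standing upright"
    with pytest.raises(SchemaError):
        PostureLabel(4)


def test_point_count_tracks_points():
    f = PointCloudFrame(0, 0.0, [[0, 0, 0], [1, 1, 1]], [(0, [0.5, 0.5, 1.0])])
    assert f.point_count == 2
    assert PointCloudFrame(1, 0.1, []).point_count == 0


def test_non_finite_coordinates_rejected():
    with pytest.raises(SchemaError):
        PointCloudFrame(0, 0.0, [[np.nan, 0, 0]])
    with pytest.raises(SchemaError):
        PointCloudFrame(0, 0.0, [], [(0, [np.inf, 0, 0])])


def test_label_frame_length_mismatch_rejected():
    frames = [PointCloudFrame(i, i / 10.0, [[0, 0, 1]]) for i in range(3)]
    with pytest.raises(SchemaError, match="labels length"):
        SubjectTrack("s", "walk", frames, [1, 1])


def test_timestamp_step_enforced():
    frames = [
        PointCloudFrame(0, 0.0, []),
        PointCloudFrame(1, 0.1, []),
        PointCloudFrame(2, 0.15, []),
    ]
    with pytest.raises(SchemaError, match="deviates"):
        SubjectTrack("s", "walk", frames, [1, 1, 1])


def _toy_track(n=4, with_truth=True):
    rng = np.random.default_rng(7)
    frames = [
        PointCloudFrame(
            i, i / 10.0, rng.normal(0, 1, (3, 3)), [(0, rng.normal(0, 1, 3))]
        )
        for i in range(n)
    ]
    truth = None
    if with_truth:
        truth = GroundTruth(
            body_center=rng.normal(0, 1, (n, 3)),
            posture=np.ones(n, dtype=int),
            fall_frame=2,
            sit_intervals=[(0, 1)],
        )
    return SubjectTrack("toy", "fall", frames, np.ones(n, dtype=int), truth=truth)


@pytest.mark.parametrize("fmt", ["jsonl", "csv"])
def test_round_trip_identity(tmp_path, fmt):
    track = _toy_track()
    p = tmp_path / f"t.{fmt}"
    write_track(track, p, fmt)
    assert read_track(p, fmt) == track


@pytest.mark.parametrize("fmt", ["jsonl", "csv"])
def test_deterministic_bytes(tmp_path, fmt):
    track = _toy_track()
    p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
    write_track(track, p1, fmt)
    write_track(track, p2, fmt)
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_track_writes_header_only(tmp_path):
    track = SubjectTrack("empty", "walk", [], [])
    p = tmp_path / "e.jsonl"
    write_track(track, p)
    lines = p.read_text().strip().splitlines()
    assert len(lines) == 1  # metadata only, zero frame records
    assert read_track(p) == track


def test_csv_records_per_entity(tmp_path):
    frame = PointCloudFrame(0, 0.0, np.arange(12.0).reshape(4, 3), [(0, [1, 1, 1])])
    track = SubjectTrack("s", "walk", [frame], [1])
    p = tmp_path / "t.csv"
    write_track(track, p)
    body = [l for l in p.read_text().splitlines() if l and not l.startswith(("#", "frame,kind"))]
    kinds = [l.split(",")[1] for l in body]
    assert kinds.count("point") == 4
    assert kinds.count("spot") == 1
    assert kinds.count("frame") == 1


def test_handwritten_jsonl_point_counts(tmp_path):
    header = {
        "schema": "pointfall-track-v1", "subject_id": "hand", "scenario": "walk",
        "room": [4, 5, 2.7], "sensor_pose": [2.5, 45], "frame_rate": 10.0,
        "n_frames": 3, "truth": None,
    }
    lines = [json.dumps(header)]
    for i, npts in enumerate([2, 0, 5]):
        lines.append(json.dumps({
            "frame": i, "label": 1,
            "points": [[0.1 * j, 0.2, 1.0] for j in range(npts)], "spots": [],
        }))
    p = tmp_path / "hand.jsonl"
    p.write_text("\n".join(lines))
    track = read_track(p)
    assert list(track.point_counts()) == [2, 0, 5]


def test_non_monotone_timestamps_rejected(tmp_path):
    header = {
        "schema": "pointfall-track-v1", "subject_id": "bad", "scenario": "walk",
        "room": [4, 5, 2.7], "sensor_pose": [2.5, 45], "frame_rate": 10.0,
        "n_frames": 3, "truth": None,
    }
    lines = [json.dumps(header)] + [
        json.dumps({"frame": i, "label": 1, "points": [], "spots": []}) for i in (0, 1, 1)
    ]
    p = tmp_path / "bad.jsonl"
    p.write_text("\n".join(lines))
    with pytest.raises(SchemaError, match="non-monotone timestamps"):
        read_track(p)


def test_malformed_record_names_line(tmp_path):
    p = tmp_path / "broken.jsonl"
    good = _toy_track(2)
    write_track(good, p)
    text = p.read_text().splitlines()
    text[2] = "{not json"
    p.write_text("\n".join(text))
    with pytest.raises(SchemaError, match=":3:"):
        read_track(p)


@st.composite
def tracks(draw):
    n = draw(st.integers(min_value=0, max_value=5))
    rng = np.random.default_rng(draw(st.integers(0, 2**20)))
    frames = []
    for i in range(n):
        npts = draw(st.integers(0, 4))
        nspots = draw(st.integers(0, 2))
        frames.append(
            PointCloudFrame(
                i, i / 10.0, rng.normal(0, 2, (npts, 3)),
                [(s, rng.normal(0, 2, 3)) for s in range(nspots)],
            )
        )
    labels = [draw(st.sampled_from([1, 2, 3])) for _ in range(n)]
    scenario = draw(st.sampled_from(["walk", "fall", "sit_cycle"]))
    return SubjectTrack("prop", scenario, frames, labels)


@settings(max_examples=25, deadline=None)
@given(tracks(), st.sampled_from(["jsonl", "csv"]))
def test_round_trip_property(tmp_path_factory, track, fmt):
    p = tmp_path_factory.mktemp("rt") / f"t.{fmt}"
    write_track(track, p, fmt)
    assert read_track(p, fmt) == track
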