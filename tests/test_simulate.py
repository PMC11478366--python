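"""Synthetic scene generator: calibration, scripts and artifacts."""

import io

import numpy as np
import pytest

from pointfall.core import CLASS_SITTING, CLASS_STANDING, ParameterError
from pointfall.features import plane_eccentricity
from pointfall.io import write_track
from pointfall.kinematics import spot_speed
from pointfall.simulate import (
    ScenarioSpec,
    generate_study_dataset,
    inject_artifacts,
    simulate_fall,
    simulate_sit_cycle,
    simulate_walk,
    synthesize_frame,
)


def _serialized(track, tmp_path, name):
    p = tmp_path / name
    write_track(track, p)
    return p.read_bytes()


def test_fixed_seed_reproduces_track_bytes(tmp_path):
    spec = ScenarioSpec(kind="walk", duration_s=10)
    a = _serialized(simulate_walk(spec, 5), tmp_path, "a.jsonl")
    b = _serialized(simulate_walk(spec, 5), tmp_path, "b.jsonl")
    assert a == b


def test_walk_speed_within_cap():
    spec = ScenarioSpec(kind="walk", duration_s=30)
    for seed in range(1, 6):
        s = spot_speed(simulate_walk(spec, seed))
        assert np.nanmax(np.abs(s.vx)) <= 1.0
        assert np.nanmax(np.abs(s.vy)) <= 1.0


def test_walk_rejects_bad_duration():
    with pytest.raises(ParameterError):
        ScenarioSpec(kind="walk", duration_s=-3)


def test_spot_height_grows_with_distance(rng):
    spec = ScenarioSpec(kind="walk")
    near = [synthesize_frame(0, np.array([2.0, 1.0]), spec, rng) for _ in range(40)]
    far = [synthesize_frame(0, np.array([2.0, 4.0]), spec, rng) for _ in range(40)]
    z_near = np.mean([f.spots[0][1][2] for f in near])
    z_far = np.mean([f.spots[0][1][2] for f in far])
    assert z_far > z_near


def test_point_count_decreases_with_distance(rng):
    spec = ScenarioSpec(kind="walk")
    near = np.mean([synthesize_frame(0, np.array([2.0, 1.0]), spec, rng).point_count for _ in range(60)])
    far = np.mean([synthesize_frame(0, np.array([2.0, 4.0]), spec, rng).point_count for _ in range(60)])
    assert far < near


class TestFall:
    def test_post_fall_quiescence_and_floor(self):
        for seed in (1, 2, 3):
            tr = simulate_fall(ScenarioSpec(kind="fall"), seed)
            t = tr.truth.fall_frame
            s = spot_speed(tr)
            post = slice(t + 10, t + 50)
            assert np.nanmean(s.horizontal()[post]) < 0.1
            assert tr.truth.body_center[-1, 2] < 0.5

    def test_point_collapse_near_fall_instant(self):
        for seed in (4, 5, 6):
            tr = simulate_fall(ScenarioSpec(kind="fall"), seed)
            counts = tr.point_counts()
            assert abs(int(np.argmin(counts)) - tr.truth.fall_frame) <= 5

    def test_labels_switch_at_onset(self):
        tr = simulate_fall(ScenarioSpec(kind="fall"), 7)
        assert tr.labels[0] == CLASS_STANDING
        assert tr.labels[-1] == 3
        switches = np.flatnonzero(np.diff(tr.labels))
        assert len(switches) == 1

    def test_early_fall_frame_rejected(self):
        with pytest.raises(ParameterError, match="peri-window"):
            simulate_fall(ScenarioSpec(kind="fall", fall_frame=10), 1)


@pytest.fixture(scope="module")
def track():
    return simulate_sit_cycle(ScenarioSpec(kind="sit_cycle"), 11)


class TestSitCycle:
    def test_five_sitting_runs(self, track):
        runs = np.flatnonzero(np.diff(track.labels)) + 1
        codes = [track.labels[0], *track.labels[runs]]
        assert codes.count(CLASS_SITTING) == 5

    def test_cloud_compacts_above_body_center(self, track):
        seated = track.labels == CLASS_SITTING
        cloud_z = np.array([f.points[:, 2].mean() for f in track.frames])
        assert cloud_z[seated].mean() > track.truth.body_center[seated, 2].mean()

    def test_seated_rounder_than_standing(self, track):
        seated_idx = np.flatnonzero(track.labels == CLASS_SITTING)[20:40]
        standing_idx = np.flatnonzero(track.labels == CLASS_STANDING)[:20]
        def mean_ecc(idx):
            vals = []
            for i in idx:
                pts = track.frames[i].points
                if len(pts) >= 4:
                    vals.append(plane_eccentricity(pts, "XZ"))
                    vals.append(plane_eccentricity(pts, "YZ"))
            return np.mean(vals)
        assert mean_ecc(seated_idx) < mean_ecc(standing_idx)

    def test_chair_outside_room_rejected(self):
        with pytest.raises(ParameterError, match="chair"):
            simulate_sit_cycle(ScenarioSpec(kind="sit_cycle", chair_distance=5.0,
                                            room=(4.0, 3.0, 2.7)), 1)


class TestArtifacts:
    def test_empty_mode_set_is_identity(self):
        tr = simulate_walk(ScenarioSpec(kind="walk", duration_s=5), 1)
        assert inject_artifacts(tr, (), 1) is tr

    def test_double_spot_spans_have_two_spots(self):
        tr = simulate_walk(ScenarioSpec(kind="walk", duration_s=20), 2)
        out = inject_artifacts(tr, ("double_spot",), 2)
        n_spots = np.array([len(f.spots) for f in out.frames])
        assert n_spots.max() == 2
        assert (n_spots == 2).sum() >= 3
        assert np.array_equal(out.labels, tr.labels)

    def test_dropout_then_low_reconstruction(self):
        tr = simulate_walk(ScenarioSpec(kind="walk", duration_s=20), 3)
        out = inject_artifacts(tr, ("spot_dropout_low",), 3)
        n_spots = np.array([len(f.spots) for f in out.frames])
        assert (n_spots == 0).any()
        zs = [f.spots[0][1][2] for f in out.frames if f.spots]
        assert min(zs) < 0.5  # reinstated near the lower legs

    def test_metal_clutter_reflects_with_empty_room(self):
        from pointfall.core import PointCloudFrame, SubjectTrack

        frames = [PointCloudFrame(i, i / 10.0, []) for i in range(10)]
        empty = SubjectTrack("nobody", "walk", frames, np.ones(10, dtype=int))
        out = inject_artifacts(empty, ("metal_clutter",), 5)
        assert all(f.point_count > 0 for f in out.frames)

    def test_unknown_mode_rejected(self):
        tr = simulate_walk(ScenarioSpec(kind="walk", duration_s=5), 1)
        with pytest.raises(ParameterError, match="unknown artifact"):
            inject_artifacts(tr, ("ghost",), 1)


@pytest.fixture(scope="module")
def small():
    return generate_study_dataset(9, n_fall=3, n_sit=3)


class TestStudyDataset:
    def test_default_protocol_counts(self):
        tracks = generate_study_dataset(1, n_fall=2, n_sit=3)
        assert len(tracks) == 5
        assert sum(t.scenario == "fall" for t in tracks) == 2
        assert len({t.subject_id for t in tracks}) == 5

    def test_tracks_valid_and_nonempty(self, small):
        for t in small:
            assert len(t) > 0
            assert len(t.labels) == len(t.frames)

    def test_seed_changes_coordinates_not_script(self):
        a = generate_study_dataset(1, n_fall=1, n_sit=1)
        b = generate_study_dataset(2, n_fall=1, n_sit=1)
        assert [t.scenario for t in a] == [t.scenario for t in b]
        assert not np.allclose(a[0].frames[0].points[:1], b[0].frames[0].points[:1])

    def test_mixed_rooms(self, small):
        assert {t.room[1] for t in small} == {3.0, 5.0}
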