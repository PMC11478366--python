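"""Synthetic indoor radar scenes.

Generates labeled :class:`~pointfall.core.SubjectTrack` objects that reproduce
the statistical structure of a ceiling-mounted MIMO radar tracker's output:

* a per-frame Gaussian point cloud around the body, whose expected point count
  *decreases* with distance from the sensor and collapses at the fall instant;
* a person spot near upper-torso height whose z coordinate *grows* with
  distance from the sensor (close to the device only part of the body is in
  the beam, so the reconstructed height drops);
* walking speeds within ±1 m/s per horizontal axis, a sharp speed spike and
  z-drop at falls, and near-zero motion in the first seconds after a fall;
* point-cloud compaction toward the upper torso when seated — the cloud
  centroid sits *above* the true body centroid and becomes nearly isotropic;
* optional tracker artifacts: a spurious second spot at knee height, spot
  dropout followed by a low (lower-leg) reconstruction, and static metallic
  clutter.

Body model: each posture is a 3-axis Gaussian point source.  Standing is tall
and thin (σ ≈ 0.15/0.15/0.45 m around mid-torso), seated is near-isotropic at
torso height, fallen is horizontal and flat at ≈ 0.2 m.  Fall kinematics are a
half-cosine descent of the spot over 6–8 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    CLASS_FALLING,
    CLASS_SITTING,
    CLASS_STANDING,
    GroundTruth,
    ParameterError,
    PointCloudFrame,
    SubjectTrack,
)

__all__ = [
    "NoiseSpec",
    "ScenarioSpec",
    "GroundTruth",
    "simulate_walk",
    "simulate_fall",
    "simulate_sit_cycle",
    "inject_artifacts",
    "generate_study_dataset",
    "ARTIFACT_MODES",
]

ARTIFACT_MODES = ("double_spot", "spot_dropout_low", "metal_clutter")

# Posture-dependent cloud geometry: (sigma_long, sigma_lat, sigma_z,
# cloud-centre height, body-centre height).
_STANDING = dict(sigma=(0.15, 0.15, 0.45), cloud_z=0.92, body_z=0.90)
_SEATED = dict(sigma=(0.18, 0.18, 0.20), cloud_z=0.95, body_z=0.55)
_FALLEN = dict(sigma=(0.45, 0.18, 0.12), cloud_z=0.20, body_z=0.20)

# Spot height model: z = base + gain * horizontal distance from sensor.
_SPOT_MODEL = {
    CLASS_STANDING: (0.88, 0.12),
    CLASS_SITTING: (0.82, 0.05),
    CLASS_FALLING: (0.20, 0.01),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic texture of the synthetic sensor.

    point_base/point_slope set the expected cloud size as a linearly
    decreasing function of sensor distance (points ~ Poisson, floored);
    fall_point_factor scales that mean during the fall transient.
    """

    spot_jitter: float = 0.005  # m, per-axis spot position noise
    point_base: float = 42.0  # expected points at distance 0
    point_slope: float = 6.0  # points lost per metre of distance
    point_floor: int = 5  # minimum expected points
    fall_point_factor: float = 0.25
    body_bob: float = 0.012  # m, vertical gait oscillation amplitude


@dataclass(frozen=True)
class ScenarioSpec:
    """Script of one synthetic acquisition."""

    kind: str  # walk | fall | sit_cycle
    duration_s: Optional[float] = None  # default depends on kind
    room: tuple[float, float, float] = (4.0, 5.0, 2.7)
    sensor_pose: tuple[float, float] = (2.5, 45.0)
    frame_rate: float = 10.0
    speed_cap: float = 1.0  # m/s, per-axis walking bound
    chair_distance: float = 2.5  # m from the sensor
    repetitions: int = 5  # sit/stand cycles
    fixed_y: bool = False  # walk toward the chair on a fixed-y line
    fall_frame: Optional[int] = None  # fixed fall onset; drawn when None
    artifact_modes: tuple[str, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.speed_cap <= 0:
            raise ParameterError("speed_cap must be positive")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ParameterError("duration must be positive")

    @property
    def sensor_xy(self) -> np.ndarray:
        return np.array([self.room[0] / 2.0, 0.0])


def _default_duration(kind: str, spec: ScenarioSpec) -> float:
    if kind == "walk":
        return 60.0
    if kind == "fall":
        return 30.0
    raise ParameterError(f"no default duration for kind {kind!r}")


def _distance(xy: np.ndarray, spec: ScenarioSpec) -> float:
    return float(np.hypot(*(np.asarray(xy) - spec.sensor_xy)))


def _spot_height(distance: float, posture: int) -> float:
    base, gain = _SPOT_MODEL[posture]
    return base + gain * distance


def _heading_rotation(heading: float) -> np.ndarray:
    c, s = math.cos(heading), math.sin(heading)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def synthesize_frame(
    index: int,
    body_xy: np.ndarray,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    posture: int = CLASS_STANDING,
    phase: float = 1.0,
    heading: float = 0.0,
    count_factor: float = 1.0,
    spot_z: Optional[float] = None,
) -> PointCloudFrame:
    """Sample one sensor frame for a body at *body_xy*.

    *phase* interpolates the cloud geometry between standing (0) and the
    target *posture* (1), which models sit-down / fall transitions.
    """
    d = _distance(body_xy, spec)
    start = _STANDING
    end = {CLASS_STANDING: _STANDING, CLASS_SITTING: _SEATED, CLASS_FALLING: _FALLEN}[posture]
    sigma = (1 - phase) * np.array(start["sigma"]) + phase * np.array(end["sigma"])
    cloud_z = (1 - phase) * start["cloud_z"] + phase * end["cloud_z"]

    mean_count = max(
        float(spec.noise.point_floor),
        count_factor * (spec.noise.point_base - spec.noise.point_slope * d),
    )
    n_points = max(0, int(rng.poisson(mean_count)))
    local = rng.standard_normal((n_points, 3)) * sigma
    rot = _heading_rotation(heading)
    centre = np.array([body_xy[0], body_xy[1], cloud_z])
    points = centre + local @ rot.T
    points[:, 2] = np.clip(points[:, 2], 0.0, spec.room[2])

    if spot_z is None:
        sz = (1 - phase) * _spot_height(d, CLASS_STANDING) + phase * _spot_height(d, posture)
    else:
        sz = spot_z
    spot = np.array([body_xy[0], body_xy[1], sz]) + rng.normal(0.0, spec.noise.spot_jitter, 3)
    return PointCloudFrame(index, index / spec.frame_rate, points, [(0, spot)])


# ---------------------------------------------------------------------------
# trajectory synthesis


def _walk_path(
    rng: np.random.Generator,
    spec: ScenarioSpec,
    n: int,
    start: Optional[np.ndarray] = None,
    margin: float = 0.4,
) -> np.ndarray:
    """Waypoint-following random walk with per-axis speed below the cap.

    Target cruise speed is drawn per leg in [0.35, 0.75] of a metre per
    second, acceleration-limited, and each velocity component is clipped to
    0.8 × speed_cap so finite-difference spot speeds (cap 1 m/s by default)
    stay in band even with spot jitter on top.
    """
    w, dep = spec.room[0], spec.room[1]
    lo = np.array([margin, margin])
    hi = np.array([w - margin, dep - margin])
    dt = 1.0 / spec.frame_rate
    axis_cap = 0.8 * spec.speed_cap
    accel = 1.2  # m/s^2

    pos = np.empty((n, 2))
    pos[0] = start if start is not None else rng.uniform(lo, hi)
    vel = np.zeros(2)
    target = rng.uniform(lo, hi)
    cruise = rng.uniform(0.35, 0.75) * spec.speed_cap
    for t in range(1, n):
        to_target = target - pos[t - 1]
        dist = np.linalg.norm(to_target)
        if dist < 0.15:
            target = rng.uniform(lo, hi)
            cruise = rng.uniform(0.35, 0.75) * spec.speed_cap
            to_target = target - pos[t - 1]
            dist = np.linalg.norm(to_target)
        desired = to_target / max(dist, 1e-9) * min(cruise, dist / dt)
        dv = np.clip(desired - vel, -accel * dt, accel * dt)
        vel = np.clip(vel + dv, -axis_cap, axis_cap)
        pos[t] = np.clip(pos[t - 1] + vel * dt, lo, hi)
    return pos


def _segment_path(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Straight-line walk from a to b over n frames with smooth ramps."""
    u = np.linspace(0.0, 1.0, n)
    ease = 0.5 * (1 - np.cos(np.pi * u))  # zero end-point speeds
    return a + np.outer(ease, b - a)


# ---------------------------------------------------------------------------
# scenario generators


def simulate_walk(spec: ScenarioSpec, seed: int) -> SubjectTrack:
    """A person walking randomly at normal speed; all frames labeled standing."""
    if spec.kind != "walk":
        raise ParameterError(f"expected kind 'walk', got {spec.kind!r}")
    rng = np.random.default_rng(seed)
    duration = spec.duration_s or _default_duration("walk", spec)
    n = int(round(duration * spec.frame_rate))
    path = _walk_path(rng, spec, n)
    frames, centers = [], np.empty((n, 3))
    for t in range(n):
        bob = spec.noise.body_bob * math.sin(2 * math.pi * 1.8 * t / spec.frame_rate)
        frames.append(synthesize_frame(t, path[t], spec, rng, CLASS_STANDING, phase=0.0))
        centers[t] = (*path[t], _STANDING["body_z"] + bob)
    truth = GroundTruth(centers, np.full(n, CLASS_STANDING))
    track = SubjectTrack(
        subject_id=f"walk-{seed}",
        scenario="walk",
        frames=frames,
        labels=np.full(n, CLASS_STANDING),
        room=spec.room,
        sensor_pose=spec.sensor_pose,
        frame_rate=spec.frame_rate,
        truth=truth,
    )
    return inject_artifacts(track, spec.artifact_modes, seed) if spec.artifact_modes else track


def _scripted_fall_z(z0: float, z1: float, n_desc: int) -> np.ndarray:
    """Noise-free half-cosine spot descent from z0 to z1 over n_desc steps."""
    u = np.linspace(0.0, 1.0, n_desc + 1)
    return z0 + (z1 - z0) * 0.5 * (1 - np.cos(np.pi * u))


def simulate_fall(spec: ScenarioSpec, seed: int) -> SubjectTrack:
    """A short walk ending in a fall: speed spike, z drop, point-count collapse.

    truth.fall_frame marks the scripted frame of maximum negative spot-z
    variation (the convention the fall detector recovers).
    """
    if spec.kind != "fall":
        raise ParameterError(f"expected kind 'fall', got {spec.kind!r}")
    rng = np.random.default_rng(seed)
    duration = spec.duration_s or _default_duration("fall", spec)
    n = int(round(duration * spec.frame_rate))
    onset = spec.fall_frame if spec.fall_frame is not None else int(rng.integers(int(0.55 * n), int(0.70 * n)))
    peri_half = 20
    if onset <= peri_half:
        raise ParameterError(
            f"fall frame {onset} lies within the first peri-window half ({peri_half} frames)"
        )
    n_desc = int(rng.integers(5, 8))  # 0.5–0.7 s descent
    if onset + n_desc >= n - 2:
        raise ParameterError("fall too close to the end of the track")

    path = _walk_path(rng, spec, onset)
    heading = math.atan2(*(path[-1] - path[-5])[::-1]) if onset >= 5 else 0.0
    frames: list[PointCloudFrame] = []
    centers = np.empty((n, 3))
    labels = np.full(n, CLASS_STANDING)
    labels[onset:] = CLASS_FALLING

    # scripted spot z over the descent, used both for generation and truth
    d_at_fall = _distance(path[-1], spec)
    z_top = _spot_height(d_at_fall, CLASS_STANDING)
    z_floor = _spot_height(d_at_fall, CLASS_FALLING)
    z_script = _scripted_fall_z(z_top, z_floor, n_desc)
    fall_frame = onset + int(np.argmin(np.diff(z_script))) + 1

    lurch = 0.30  # forward displacement while falling, m
    fall_dir = np.array([math.cos(heading), math.sin(heading)])
    final_xy = path[-1] + lurch * fall_dir

    for t in range(n):
        if t < onset:
            bob = spec.noise.body_bob * math.sin(2 * math.pi * 1.8 * t / spec.frame_rate)
            frames.append(synthesize_frame(t, path[t], spec, rng, CLASS_STANDING, phase=0.0))
            centers[t] = (*path[t], _STANDING["body_z"] + bob)
        elif t <= onset + n_desc:
            u = (t - onset) / n_desc
            xy = path[-1] + lurch * (0.5 * (1 - math.cos(math.pi * u))) * fall_dir
            factor = spec.noise.fall_point_factor
            frames.append(
                synthesize_frame(
                    t, xy, spec, rng, CLASS_FALLING, phase=u, heading=heading,
                    count_factor=factor, spot_z=float(z_script[t - onset]),
                )
            )
            centers[t] = (*xy, (1 - u) * _STANDING["body_z"] + u * _FALLEN["body_z"])
        else:
            factor = spec.noise.fall_point_factor if t <= onset + n_desc + 1 else 1.0
            frames.append(
                synthesize_frame(
                    t, final_xy, spec, rng, CLASS_FALLING, phase=1.0, heading=heading,
                    count_factor=factor, spot_z=float(z_script[-1]),
                )
            )
            centers[t] = (*final_xy, _FALLEN["body_z"])

    truth = GroundTruth(centers, labels.copy(), fall_frame=fall_frame)
    track = SubjectTrack(
        subject_id=f"fall-{seed}",
        scenario="fall",
        frames=frames,
        labels=labels,
        room=spec.room,
        sensor_pose=spec.sensor_pose,
        frame_rate=spec.frame_rate,
        truth=truth,
    )
    return inject_artifacts(track, spec.artifact_modes, seed) if spec.artifact_modes else track


def simulate_sit_cycle(spec: ScenarioSpec, seed: int) -> SubjectTrack:
    """Enter → sit on the chair → stand → return, repeated; labels 1/2.

    While seated the cloud contracts toward the upper torso: its centroid
    rises above the true body centre and its shape becomes near-isotropic.
    The ``fixed_y`` variant walks to the chair along a fixed-y line, keeping
    sensor distance (hence point count and spot height) roughly stable.
    """
    if spec.kind != "sit_cycle":
        raise ParameterError(f"expected kind 'sit_cycle', got {spec.kind!r}")
    rng = np.random.default_rng(seed)
    w, dep = spec.room[0], spec.room[1]
    chair = np.array([w / 2.0, spec.chair_distance])
    if not (0.3 <= chair[1] <= dep - 0.3):
        raise ParameterError(f"chair at {spec.chair_distance} m lies outside the room depth {dep} m")
    door = np.array([0.4, chair[1]]) if spec.fixed_y else np.array([0.4, 0.4])

    rate = spec.frame_rate
    walk_speed = 0.5  # m/s along scripted segments
    n_walk = max(2, int(round(np.linalg.norm(chair - door) / walk_speed * rate)))
    n_trans = int(round(1.0 * rate))  # sit-down / stand-up
    n_seated = int(round(5.0 * rate))

    frames: list[PointCloudFrame] = []
    centers: list[tuple[float, float, float]] = []
    labels: list[int] = []
    sit_intervals: list[tuple[int, int]] = []
    t = 0

    def emit(xy, posture, phase, label, body_z):
        nonlocal t
        frames.append(synthesize_frame(t, np.asarray(xy), spec, rng, posture, phase=phase))
        centers.append((xy[0], xy[1], body_z))
        labels.append(label)
        t += 1

    for _ in range(spec.repetitions):
        for xy in _segment_path(door, chair, n_walk):
            emit(xy, CLASS_STANDING, 0.0, CLASS_STANDING, _STANDING["body_z"])
        sit_start = t
        for k in range(n_trans):
            u = (k + 1) / n_trans
            bz = (1 - u) * _STANDING["body_z"] + u * _SEATED["body_z"]
            emit(chair, CLASS_SITTING, u, CLASS_SITTING, bz)
        for _k in range(n_seated):
            emit(chair, CLASS_SITTING, 1.0, CLASS_SITTING, _SEATED["body_z"])
        for k in range(n_trans):
            u = (k + 1) / n_trans
            bz = (1 - u) * _SEATED["body_z"] + u * _STANDING["body_z"]
            emit(chair, CLASS_SITTING if u < 1.0 else CLASS_STANDING, 1.0 - u,
                 CLASS_SITTING if u < 1.0 else CLASS_STANDING, bz)
        sit_intervals.append((sit_start, t - 1))
        for xy in _segment_path(chair, door, n_walk):
            emit(xy, CLASS_STANDING, 0.0, CLASS_STANDING, _STANDING["body_z"])

    n = t
    truth = GroundTruth(
        np.asarray(centers), np.asarray(labels), sit_intervals=sit_intervals
    )
    track = SubjectTrack(
        subject_id=f"sit-{seed}",
        scenario="sit_cycle",
        frames=frames,
        labels=np.asarray(labels),
        room=spec.room,
        sensor_pose=spec.sensor_pose,
        frame_rate=spec.frame_rate,
        truth=truth,
    )
    return inject_artifacts(track, spec.artifact_modes, seed) if spec.artifact_modes else track


# ---------------------------------------------------------------------------
# artifacts


def _copy_frame(frame: PointCloudFrame) -> PointCloudFrame:
    return PointCloudFrame(
        frame.frame_index, frame.timestamp, frame.points.copy(),
        [(sid, xyz.copy()) for sid, xyz in frame.spots],
    )


def inject_artifacts(track: SubjectTrack, modes: Sequence[str], seed: int) -> SubjectTrack:
    """Overlay tracker failure modes on a track; ground truth is unchanged.

    double_spot adds a spurious knee-height spot for random spans;
    spot_dropout_low removes the spot briefly, then reinstates it near the
    lower legs; metal_clutter adds a small static reflection cluster.
    """
    modes = tuple(modes)
    unknown = set(modes) - set(ARTIFACT_MODES)
    if unknown:
        raise ParameterError(f"unknown artifact modes {sorted(unknown)}; known: {ARTIFACT_MODES}")
    if not modes:
        return track
    rng = np.random.default_rng(seed + 7919)
    frames = [_copy_frame(f) for f in track.frames]
    n = len(frames)

    if "double_spot" in modes and n > 10:
        span = max(3, int(rng.integers(int(0.05 * n), int(0.15 * n) + 1)))
        start = int(rng.integers(0, n - span))
        for f in frames[start : start + span]:
            if f.spots:
                sid, xyz = f.spots[0]
                knee = xyz.copy()
                knee[2] = 0.45 + rng.normal(0.0, 0.02)
                f.spots = (*f.spots, (sid + 1, knee))

    if "spot_dropout_low" in modes and n > 30:
        gap = int(rng.integers(3, 6))
        low = int(rng.integers(8, 13))
        start = int(rng.integers(10, n - gap - low - 1))
        for f in frames[start : start + gap]:
            f.spots = ()
        for f in frames[start + gap : start + gap + low]:
            if f.spots:
                sid, xyz = f.spots[0]
                xyz[2] = 0.30 + rng.normal(0.0, 0.02)

    if "metal_clutter" in modes:
        corner = np.array([track.room[0] - 0.5, track.room[1] - 0.5, 0.6])
        cluster_rng = np.random.default_rng(seed + 104729)
        for f in frames:
            clutter = corner + cluster_rng.normal(0.0, 0.05, (int(cluster_rng.integers(3, 7)), 3))
            clutter[:, 2] = np.clip(clutter[:, 2], 0.0, track.room[2])
            f.points = np.vstack([f.points, clutter]) if f.point_count else clutter

    return SubjectTrack(
        subject_id=track.subject_id,
        scenario=track.scenario,
        frames=frames,
        labels=track.labels.copy(),
        room=track.room,
        sensor_pose=track.sensor_pose,
        frame_rate=track.frame_rate,
        truth=track.truth,
    )


# ---------------------------------------------------------------------------
# study protocol


def generate_study_dataset(
    seed: int,
    n_fall: int = 12,
    n_sit: int = 14,
) -> list[SubjectTrack]:
    """The default synthetic study: 12 fall tracks + 14 sit/walk tracks.

    Distinct synthetic subjects, rooms alternating between 4×3 m and 4×5 m,
    half of the sit tracks using the fixed-y chair approach.  Deterministic
    for a fixed seed.
    """
    seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seq.spawn(n_fall + n_sit)]
    rooms = [(4.0, 5.0, 2.7), (4.0, 3.0, 2.7)]
    tracks: list[SubjectTrack] = []
    for i in range(n_fall):
        spec = ScenarioSpec(kind="fall", room=rooms[i % 2])
        tr = simulate_fall(spec, child_seeds[i])
        tr.subject_id = f"S{i + 1:02d}"
        tracks.append(tr)
    for j in range(n_sit):
        spec = ScenarioSpec(kind="sit_cycle", room=rooms[j % 2], fixed_y=(j % 2 == 1))
        tr = simulate_sit_cycle(spec, child_seeds[n_fall + j])
        tr.subject_id = f"S{n_fall + j + 1:02d}"
        tracks.append(tr)
    return tracks
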