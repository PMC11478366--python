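"""Domain types for radar point-cloud posture tracks.

A millimetre-wave MIMO radar tracker emits, at a fixed frame rate, a *point
cloud* (3D reflection points) and zero or more *spots* — one per-person anchor
nominally placed at upper-torso height.  These types hold one acquisition
("track") of such output together with per-frame posture labels and, for
synthetic data, the generating ground truth.

Coordinate convention: right-handed, metres, z up, floor at z = 0.  The sensor
pose (mounting height, tilt) is carried as metadata; all stored coordinates are
already in the room frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CLASS_STANDING",
    "CLASS_SITTING",
    "CLASS_FALLING",
    "CLASS_CODES",
    "CLASS_NAMES",
    "PointfallError",
    "SchemaError",
    "ParameterError",
    "PostureLabel",
    "PointCloudFrame",
    "GroundTruth",
    "SubjectTrack",
]

#: Posture class codes used throughout the package.
CLASS_STANDING = 1
CLASS_SITTING = 2
CLASS_FALLING = 3
CLASS_CODES = (CLASS_STANDING, CLASS_SITTING, CLASS_FALLING)
CLASS_NAMES = {1: "standing upright", 2: "sitting", 3: "falling"}


class PointfallError(Exception):
    """Base class for all package errors."""


class SchemaError(PointfallError):
    """A track or frame violates the data schema or a type invariant."""


class ParameterError(PointfallError):
    """An operation was called with out-of-range parameters."""


@dataclass(frozen=True)
class PostureLabel:
    """One of the three posture classes (1 standing, 2 sitting, 3 falling)."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise SchemaError(f"posture code must be one of {CLASS_CODES}, got {self.code!r}")

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.code]


def _as_points(points: Iterable) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise SchemaError(f"points must be an (n, 3) array, got shape {arr.shape}")
    return arr


class PointCloudFrame:
    """One sensor tick: a point cloud plus zero or more person spots.

    Parameters
    ----------
    frame_index
        Non-negative position of the frame within its track.
    timestamp
        Seconds since track start (``frame_index / frame_rate``).
    points
        ``(n, 3)`` array of reflection points in metres, room frame.
    spots
        Sequence of ``(spot_id, xyz)`` person anchors.
    """

    __slots__ = ("frame_index", "timestamp", "points", "spots")

    def __init__(
        self,
        frame_index: int,
        timestamp: float,
        points: Iterable,
        spots: Sequence[tuple[int, Iterable]] = (),
    ) -> None:
        if frame_index < 0:
            raise SchemaError(f"frame_index must be non-negative, got {frame_index}")
        self.frame_index = int(frame_index)
        self.timestamp = float(timestamp)
        self.points = _as_points(points)
        self.spots = tuple(
            (int(sid), np.asarray(xyz, dtype=float).reshape(3)) for sid, xyz in spots
        )
        if not np.all(np.isfinite(self.points)):
            raise SchemaError(f"frame {frame_index}: non-finite point coordinates")
        for sid, xyz in self.spots:
            if not np.all(np.isfinite(xyz)):
                raise SchemaError(f"frame {frame_index}: non-finite spot {sid}")

    @property
    def point_count(self) -> int:
        return int(self.points.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PointCloudFrame):
            return NotImplemented
        return (
            self.frame_index == other.frame_index
            and math.isclose(self.timestamp, other.timestamp, abs_tol=1e-9)
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
            and len(self.spots) == len(other.spots)
            and all(
                a[0] == b[0] and np.array_equal(a[1], b[1])
                for a, b in zip(self.spots, other.spots)
            )
        )

    def __repr__(self) -> str:
        return (
            f"PointCloudFrame(frame_index={self.frame_index}, "
            f"points={self.point_count}, spots={len(self.spots)})"
        )


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic track.

    body_center is the true body centroid per frame — distinct from the cloud
    centroid, which the sensor compacts toward the upper torso when seated.
    """

    body_center: np.ndarray  # (n_frames, 3)
    posture: np.ndarray  # (n_frames,) codes in {1,2,3}
    fall_frame: Optional[int] = None
    sit_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            np.allclose(self.body_center, other.body_center)
            and np.array_equal(self.posture, other.posture)
            and self.fall_frame == other.fall_frame
            and list(map(tuple, self.sit_intervals)) == list(map(tuple, other.sit_intervals))
        )


SCENARIOS = ("walk", "fall", "sit_cycle", "combined")

DEFAULT_SENSOR_POSE = (2.5, 45.0)  # mounting height (m), downward tilt (deg)
DEFAULT_FRAME_RATE = 10.0  # Hz


class SubjectTrack:
    """One acquisition: ordered frames, per-frame labels and scenario metadata.

    Invariants enforced at construction: labels and frames have equal length,
    timestamps increase in steps of ``1 / frame_rate``, labels are valid class
    codes, coordinates are finite (checked per frame).
    """

    def __init__(
        self,
        subject_id: str,
        scenario: str,
        frames: Sequence[PointCloudFrame],
        labels: Iterable[int],
        room: tuple[float, float, float] = (4.0, 5.0, 2.7),
        sensor_pose: tuple[float, float] = DEFAULT_SENSOR_POSE,
        frame_rate: float = DEFAULT_FRAME_RATE,
        truth: Optional[GroundTruth] = None,
    ) -> None:
        if scenario not in SCENARIOS:
            raise SchemaError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
        if frame_rate <= 0:
            raise SchemaError("frame_rate must be positive")
        self.subject_id = str(subject_id)
        self.scenario = scenario
        self.frames = list(frames)
        self.labels = np.asarray(list(labels), dtype=int)
        self.room = tuple(float(v) for v in room)
        self.sensor_pose = (float(sensor_pose[0]), float(sensor_pose[1]))
        self.frame_rate = float(frame_rate)
        self.truth = truth
        self._validate()

    def _validate(self) -> None:
        if len(self.labels) != len(self.frames):
            raise SchemaError(
                f"labels length {len(self.labels)} != frames length {len(self.frames)}"
            )
        bad = set(np.unique(self.labels)) - set(CLASS_CODES)
        if bad:
            raise SchemaError(f"invalid posture codes {sorted(bad)}")
        dt = 1.0 / self.frame_rate
        prev = None
        for frame in self.frames:
            if prev is not None:
                step = frame.timestamp - prev
                if step <= 0:
                    raise SchemaError("non-monotone timestamps")
                if abs(step - dt) > 1e-6:
                    raise SchemaError(
                        f"timestamp step {step:.6f} s deviates from 1/frame_rate = {dt:.6f} s"
                    )
            prev = frame.timestamp
        if self.truth is not None and len(self.truth.posture) != len(self.frames):
            raise SchemaError("ground-truth posture length != frames length")

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def sensor_xy(self) -> tuple[float, float]:
        """Sensor location projected on the floor (mid wall at y = 0)."""
        return (self.room[0] / 2.0, 0.0)

    def point_counts(self) -> np.ndarray:
        return np.array([f.point_count for f in self.frames], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubjectTrack):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.scenario == other.scenario
            and self.room == other.room
            and self.sensor_pose == other.sensor_pose
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.labels, other.labels)
            and len(self.frames) == len(other.frames)
            and all(a == b for a, b in zip(self.frames, other.frames))
            and (
                (self.truth is None and other.truth is None)
                or (self.truth is not None and self.truth == other.truth)
            )
        )

    def __repr__(self) -> str:
        return (
            f"SubjectTrack({self.subject_id!r}, scenario={self.scenario!r}, "
            f"n_frames={len(self.frames)}, room={self.room})"
        )
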