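"""Spot-trajectory kinematics and fall-instant detection.

The person spot is the tracker's per-frame 3D anchor.  Speeds are forward
finite differences of the spot position scaled by the frame rate.  A fall is
located at the point of maximum negative variation of the spot's z
coordinate; a 40-frame peri-fall window (2 s each side at 10 Hz) and a
post-fall span (frames t*+10 … t*+50) summarize the event:

* ``peak_speed`` — the signed speed component of largest magnitude inside the
  peri-fall window (sign preserved: the peak can be positive or negative
  depending on fall direction);
* ``post_fall_mean_speed`` — mean horizontal speed right after the fall,
  expected near zero because the person moves very little at first;
* ``delta_z`` — the z drop across the peri-fall window, the most significant
  single indicator of a fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ParameterError, PointfallError, SubjectTrack

__all__ = [
    "SpeedSeries",
    "FallEvent",
    "NoSpotError",
    "primary_spot_positions",
    "spot_speed",
    "detect_fall_instant",
    "fall_window_stats",
]

DEFAULT_DZ_THRESHOLD = -0.15  # m per frame-step; see methods note
PERI_HALF = 20  # frames each side of the fall instant (40 total)
POST_LO, POST_HI = 10, 50  # post-fall span, frames after t*, inclusive


class NoSpotError(PointfallError):
    """The track contains no usable spot."""


@dataclass
class SpeedSeries:
    """Per-frame spot velocities (m/s), forward differences, length n-1."""

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    frame_rate: float

    def __len__(self) -> int:
        return len(self.vx)

    def horizontal(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def stack(self) -> np.ndarray:
        return np.stack([self.vx, self.vy, self.vz], axis=1)


@dataclass
class FallEvent:
    fall_frame: int
    peri_window: tuple[int, int]  # inclusive frame span, 40 frames when untruncated
    peak_speed: float  # signed, m/s
    post_fall_mean_speed: float  # m/s
    delta_z: float  # m, z change across the peri-fall window
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "fall_frame": self.fall_frame,
            "peri_window": list(self.peri_window),
            "peak_speed": self.peak_speed,
            "post_fall_mean_speed": self.post_fall_mean_speed,
            "delta_z": self.delta_z,
            "truncated": self.truncated,
        }


def primary_spot_positions(track: SubjectTrack, max_gap: int = 5) -> np.ndarray:
    """Resolve one primary spot position per frame, as an ``(n, 3)`` array.

    With multiple spots (e.g. a knee-height artifact) the spot nearest the
    previous primary position wins; on the first resolved frame the highest
    spot wins, since the true anchor sits at torso height while artifact
    spots appear low.  Missing frames are linearly interpolated when the gap
    is at most *max_gap* frames; longer gaps are left as NaN.
    """
    n = len(track.frames)
    if n == 0:
        raise NoSpotError("empty track")
    pos = np.full((n, 3), np.nan)
    prev: Optional[np.ndarray] = None
    for i, frame in enumerate(track.frames):
        if not frame.spots:
            continue
        candidates = [xyz for _sid, xyz in frame.spots]
        if prev is None:
            chosen = max(candidates, key=lambda p: p[2])
        else:
            chosen = min(candidates, key=lambda p: float(np.linalg.norm(p - prev)))
        pos[i] = chosen
        prev = chosen
    valid = ~np.isnan(pos[:, 0])
    if not valid.any():
        raise NoSpotError("track has no spot in any frame")
    # fill interior gaps of length <= max_gap
    idx = np.flatnonzero(valid)
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            w = np.linspace(0.0, 1.0, gap + 2)[1:-1, None]
            pos[a + 1 : b] = (1 - w) * pos[a] + w * pos[b]
    return pos


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows; NaN-tolerant."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    mask = np.isfinite(x).astype(float)
    filled = np.where(np.isfinite(x), x, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def spot_speed(track: SubjectTrack, smooth_window: int = 3, max_gap: int = 5) -> SpeedSeries:
    """Finite-difference spot velocity, optionally moving-average smoothed.

    ``v[i]`` is the velocity over the step from frame ``i`` to ``i+1``:
    ``(pos[i+1] - pos[i]) * frame_rate``.
    """
    if len(track.frames) < 2:
        raise ParameterError("speed needs at least 2 frames")
    pos = primary_spot_positions(track, max_gap=max_gap)
    vel = np.diff(pos, axis=0) * track.frame_rate
    return SpeedSeries(
        vx=_smooth(vel[:, 0], smooth_window),
        vy=_smooth(vel[:, 1], smooth_window),
        vz=_smooth(vel[:, 2], smooth_window),
        frame_rate=track.frame_rate,
    )


def detect_fall_instant(
    track: SubjectTrack,
    threshold: float = DEFAULT_DZ_THRESHOLD,
    smooth_window: int = 1,
    max_gap: int = 5,
) -> Optional[int]:
    """Locate the fall instant from the spot-z first derivative, or ``None``.

    Returns the frame at which the z drop lands: if the largest negative
    one-step variation occurs between frames ``i`` and ``i+1``, the fall
    instant is ``i + 1``.  When even the largest drop stays above *threshold*
    (m per frame step) the track is declared fall-free.  Ties break to the
    earliest frame.
    """
    if len(track.frames) < 2:
        raise ParameterError("fall detection needs at least 2 frames")
    z = primary_spot_positions(track, max_gap=max_gap)[:, 2]
    z = _smooth(z, smooth_window)
    dz = np.diff(z)
    if not np.isfinite(dz).any():
        raise NoSpotError("no contiguous spot segment to differentiate")
    dz_filled = np.where(np.isfinite(dz), dz, np.inf)
    i = int(np.argmin(dz_filled))  # argmin takes the earliest on ties
    if dz_filled[i] > threshold:
        return None
    return i + 1


def fall_window_stats(
    track: SubjectTrack,
    t_star: int,
    peri_half: int = PERI_HALF,
    post_lo: int = POST_LO,
    post_hi: int = POST_HI,
    horizontal_only: bool = True,
    smooth_window: int = 3,
) -> FallEvent:
    """Peri-fall and post-fall statistics around the fall instant *t_star*.

    The peri-fall window covers frames ``[t* - peri_half, t* + peri_half - 1]``
    (40 frames at the default), truncated with a warning on short tracks.
    """
    n = len(track.frames)
    if not 0 <= t_star < n:
        raise ParameterError(f"t_star {t_star} out of range for {n} frames")
    speeds = spot_speed(track, smooth_window=smooth_window)
    pos = primary_spot_positions(track)

    lo = t_star - peri_half
    hi = t_star + peri_half - 1  # inclusive frame span
    truncated = lo < 0 or hi > n - 1
    if truncated:
        warnings.warn(
            f"peri-fall window [{lo}, {hi}] truncated to track length {n}", stacklevel=2
        )
    lo_c, hi_c = max(lo, 0), min(hi, n - 1)

    # speed index j covers the step from frame j to j+1
    span = np.arange(lo_c, min(hi_c, len(speeds) - 1) + 1)
    peri = speeds.stack()[span]
    finite = np.isfinite(peri)
    if finite.any():
        flat = np.where(finite, peri, 0.0)
        peak = float(flat.flat[np.argmax(np.abs(flat))])
    else:
        peak = float("nan")

    post = np.arange(t_star + post_lo, min(t_star + post_hi, len(speeds) - 1) + 1)
    if len(post) == 0:
        post_mean = float("nan")
        truncated = True
    else:
        if len(post) < post_hi - post_lo + 1:
            truncated = True
            warnings.warn("post-fall span truncated to track length", stacklevel=2)
        if horizontal_only:
            vals = speeds.horizontal()[post]
        else:
            vals = np.linalg.norm(speeds.stack()[post], axis=1)
        post_mean = float(np.nanmean(vals))

    delta_z = float(pos[hi_c, 2] - pos[lo_c, 2])
    return FallEvent(
        fall_frame=int(t_star),
        peri_window=(lo_c, hi_c),
        peak_speed=peak,
        post_fall_mean_speed=post_mean,
        delta_z=delta_z,
        truncated=truncated,
    )
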