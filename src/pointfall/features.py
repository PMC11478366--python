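"""Confidence-ellipsoid reconstruction of the point cloud and frame features.

Each frame's cloud is summarized by the ellipsoid of its sample covariance:
the centre is the sample mean and the semi-axes are ``sqrt(chi2_3(q) * λ_i)``
for eigenvalues λ_i, so that for Gaussian clouds the ellipsoid covers a
fraction *q* of the points (default 95%).  Shape is captured by per-plane
eccentricities

    e = sqrt(1 - b² / a²),   a = major, b = minor in-plane semi-axis,

computed on the XY, XZ and YZ projections.  Eccentricity is invariant under
uniform scaling and in-plane rotation, and is the discriminating quantity
between postures: a standing body is elongated in z (e ≈ 0.9 in the vertical
planes) while a seated cloud compacts to a near-sphere at torso height.

The 7-dimensional per-frame descriptor fed to the classifiers is, in fixed
order: centre x, y, z, ellipsoid volume, e_xy, e_xz, e_yz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError, PointCloudFrame, PointfallError, SubjectTrack

__all__ = [
    "FEATURE_NAMES",
    "DegenerateFitError",
    "ConfidenceEllipsoid",
    "FrameFeatures",
    "fit_confidence_ellipsoid",
    "plane_eccentricity",
    "extract_features",
    "featurize_track",
]

FEATURE_NAMES = ("cx", "cy", "cz", "volume", "e_xy", "e_xz", "e_yz")

_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


class DegenerateFitError(PointfallError):
    """The point set does not support a full-rank ellipsoid fit."""

    def __init__(self, message: str, rank: int):
        super().__init__(message)
        self.rank = rank


@dataclass
class ConfidenceEllipsoid:
    center: np.ndarray  # (3,), m
    semi_axes: np.ndarray  # (3,), a >= b >= c, m
    orientation: np.ndarray  # (3, 3) rotation, rows are axis directions
    volume: float  # m^3
    plane_eccentricities: dict  # {"XY": e, "XZ": e, "YZ": e}


@dataclass
class FrameFeatures:
    cx: float
    cy: float
    cz: float
    volume: float
    e_xy: float
    e_xz: float
    e_yz: float
    stale: bool = False  # carried forward from the last valid frame

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cx, self.cy, self.cz, self.volume, self.e_xy, self.e_xz, self.e_yz]
        )


def _eccentricity_from_eigvals(lam_max: float, lam_min: float) -> float:
    # Eccentricity depends only on the axis ratio, so the confidence scaling
    # cancels and the covariance eigenvalues can be used directly.
    if lam_max <= 0:
        raise DegenerateFitError("zero in-plane scatter", rank=0)
    return float(np.sqrt(1.0 - lam_min / lam_max))


def plane_eccentricity(points: np.ndarray, plane: str) -> float:
    """Eccentricity of the cloud projected onto one coordinate plane.

    ``e = sqrt(1 - b²/a²)`` with *a* the major and *b* the minor in-plane
    semi-axis; 0 for an isotropic (circular) projection, approaching 1 for a
    collinear one.
    """
    if plane not in _PLANES:
        raise ParameterError(f"plane must be one of {tuple(_PLANES)}, got {plane!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ParameterError("need at least 3 points of dimension 3")
    proj = pts[:, _PLANES[plane]]
    cov = np.cov(proj, rowvar=False)
    lam = np.linalg.eigvalsh(cov)
    return _eccentricity_from_eigvals(float(lam[1]), float(max(lam[0], 0.0)))


def fit_confidence_ellipsoid(points: np.ndarray, confidence: float = 0.95) -> ConfidenceEllipsoid:
    """Fit the covariance confidence ellipsoid of a 3D point set.

    Centre = sample mean; axes from the eigen-decomposition of the sample
    covariance; semi-axis_i = sqrt(chi2_3(confidence) · λ_i).  Eigenvalue ties
    are broken by axis-aligned ordering (numpy's deterministic eigh order).

    Raises :class:`DegenerateFitError` (carrying the achieved covariance
    rank) for fewer than 4 points or a rank-deficient covariance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or (pts.size and pts.shape[1] != 3):
        raise ParameterError(f"points must be (n, 3), got shape {pts.shape}")
    if pts.shape[0] < 4:
        rank = 0 if pts.shape[0] < 2 else int(np.linalg.matrix_rank(pts - pts.mean(0)))
        raise DegenerateFitError(f"need >= 4 points, got {pts.shape[0]}", rank=rank)
    if not 0.0 < confidence < 1.0:
        raise ParameterError("confidence must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    lam, vec = np.linalg.eigh(cov)
    rank = int(np.sum(lam > 1e-12 * max(lam.max(), 1e-300)))
    if rank < 3 or lam[0] <= 0:
        raise DegenerateFitError(f"rank-deficient covariance (rank {rank})", rank=rank)
    scale = stats.chi2.ppf(confidence, df=3)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    semi = np.sqrt(scale * lam)
    volume = float(4.0 / 3.0 * np.pi * np.prod(semi))
    eccs = {p: plane_eccentricity(pts, p) for p in _PLANES}
    return ConfidenceEllipsoid(
        center=center,
        semi_axes=semi,
        orientation=vec.T,
        volume=volume,
        plane_eccentricities=eccs,
    )


def extract_features(frame: PointCloudFrame, confidence: float = 0.95) -> FrameFeatures:
    """The 7-feature descriptor of one frame, in the fixed column order."""
    ell = fit_confidence_ellipsoid(frame.points, confidence=confidence)
    e = ell.plane_eccentricities
    return FrameFeatures(
        cx=float(ell.center[0]),
        cy=float(ell.center[1]),
        cz=float(ell.center[2]),
        volume=ell.volume,
        e_xy=e["XY"],
        e_xz=e["XZ"],
        e_yz=e["YZ"],
    )


def featurize_track(
    track: SubjectTrack,
    confidence: float = 0.95,
    on_degenerate: str = "carry",
) -> pd.DataFrame:
    """Per-frame features of a track as a DataFrame.

    Columns: the 7 features, ``label``, ``frame``, ``stale``.  Frames whose
    fit is degenerate (too few points, e.g. during the fall point-collapse)
    either carry forward the last valid feature vector with ``stale=True``
    (default) or are dropped (``on_degenerate="drop"``).  Leading degenerate
    frames are always dropped.
    """
    if on_degenerate not in ("carry", "drop"):
        raise ParameterError("on_degenerate must be 'carry' or 'drop'")
    rows = []
    last: Optional[FrameFeatures] = None
    for frame, label in zip(track.frames, track.labels):
        try:
            feats = extract_features(frame, confidence=confidence)
            last = feats
            stale = False
        except DegenerateFitError:
            if on_degenerate == "drop" or last is None:
                continue
            feats, stale = last, True
        rows.append(
            {
                **dict(zip(FEATURE_NAMES, feats.as_array())),
                "label": int(label),
                "frame": frame.frame_index,
                "stale": stale,
            }
        )
    return pd.DataFrame(rows, columns=[*FEATURE_NAMES, "label", "frame", "stale"])
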