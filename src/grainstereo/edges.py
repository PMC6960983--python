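"""Shape-based correspondence of grains and their edge points.

Grains carry almost no surface texture, so corresponding points cannot be
matched photometrically.  Instead each grain boundary is described by its
polar-distance signature: the centroid-to-edge distance resampled at 1 degree
steps (360 values), with the polar axis along photo +x and counter-clockwise
positive.  Corresponding edge points between the two views are found by
circularly rotating one signature against the other and maximising the
Pearson correlation coefficient over all 360 integer shifts; the best shift
aligns the two angular parameterisations, pairing point i on the left edge
with point (i + k) mod 360 on the right edge.

Grain-level correspondence works in object space: the right image drives the
search — each right-image centroid is back-projected to the board plane
(Z = 0), re-projected through the left camera, and paired with the nearest
left-image centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path

from .errors import ConfigError, ProfileError
from .geometry import CameraModel
from .segmentation import GrainRegion

__all__ = [
    "EdgeProfile",
    "GrainMatch",
    "EdgeCorrespondence",
    "polar_distances",
    "resample_profile",
    "profile_from_boundary",
    "match_grains",
    "match_edge_points",
    "correspondence_to_image_points",
]

N_ANGLES = 360  # 1-degree resampling interval


@dataclass
class EdgeProfile:
    """360 centroid-to-edge distances (px) at 1-degree polar steps."""

    h: np.ndarray                 # (360,)
    centroid: np.ndarray          # (2,) photo coordinates
    label: int | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (N_ANGLES,):
            raise ConfigError(f"edge profile must have {N_ANGLES} samples")
        if np.any(self.h <= 0):
            raise ProfileError("edge profile distances must be positive")
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass(frozen=True)
class GrainMatch:
    """A left/right grain pairing with its object-space projection distance."""

    left_id: int
    right_id: int
    projected_distance: float


@dataclass
class EdgeCorrespondence:
    """Best circular shift between two edge profiles.

    ``shift`` k pairs left angle i with right angle (i + k) mod 360;
    ``correlation`` is the maximum Pearson coefficient over all 360 shifts.
    ``degenerate`` flags zero-variance profiles (a perfect circle), for
    which the shift defaults to 0.
    """

    shift: int
    correlation: float
    degenerate: bool = False

    def pairs(self) -> np.ndarray:
        i = np.arange(N_ANGLES)
        return np.column_stack([i, (i + self.shift) % N_ANGLES])


# --------------------------------------------------------------------------
# Polar signature
# --------------------------------------------------------------------------

def polar_distances(boundary, centroid) -> tuple[np.ndarray, np.ndarray]:
    """Per-boundary-point polar angle (deg, in [0, 360)) and distance (px).

    ``boundary`` is an ordered counter-clockwise closed boundary in photo
    coordinates; the output preserves that order, rolled to start at the
    point nearest the polar-axis crossing (angle closest to 0).  The
    centroid must lie strictly inside the boundary polygon (star-shaped
    silhouette assumption).
    """
    b = np.asarray(boundary, dtype=float).reshape(-1, 2)
    c = np.asarray(centroid, dtype=float).reshape(2)
    if len(b) < 3:
        raise ProfileError("boundary too short for a polar profile")
    if not Path(b).contains_point(c):
        raise ProfileError("centroid lies outside the boundary polygon")
    d = b - c
    dist = np.hypot(d[:, 0], d[:, 1])
    if np.any(dist <= 0):
        raise ProfileError("boundary point coincides with the centroid")
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    start = int(np.argmin(np.minimum(ang, 360.0 - ang)))
    ang = np.roll(ang, -start)
    dist = np.roll(dist, -start)
    return ang, dist


def resample_profile(angles, distances, *, max_gap_deg: float = 20.0) -> np.ndarray:
    """Linear interpolation of raw (angle, distance) samples at 1-degree steps.

    Samples are sorted by angle; where the rasterised boundary crosses an
    angle more than once, the outermost (largest) distance wins.  A circular
    angular gap larger than ``max_gap_deg`` marks a pathological boundary.
    Interpolation wraps at 360 -> 0 and cannot overshoot the raw range.
    """
    ang = np.asarray(angles, dtype=float).ravel() % 360.0
    d = np.asarray(distances, dtype=float).ravel()
    if ang.shape != d.shape or len(ang) < 3:
        raise ProfileError("need matching angle/distance arrays of length >= 3")
    order = np.argsort(ang, kind="stable")
    ang, d = ang[order], d[order]
    # outermost crossing per (numerically) identical angle
    keep = np.ones(len(ang), dtype=bool)
    same = np.isclose(np.diff(ang), 0.0, atol=1e-9)
    for i in np.nonzero(same)[0]:
        if d[i] >= d[i + 1]:
            d[i + 1] = d[i]
        keep[i] = False
    ang, d = ang[keep], d[keep]
    gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
    if gaps.max() > max_gap_deg:
        raise ProfileError(f"angular gap of {gaps.max():.1f} deg exceeds {max_gap_deg} deg")
    target = np.arange(N_ANGLES, dtype=float)
    return np.interp(target, ang, d, period=360.0)


def profile_from_boundary(boundary, centroid, label: int | None = None) -> EdgeProfile:
    """Polar signature of one boundary: :func:`polar_distances` then resampling."""
    ang, d = polar_distances(boundary, centroid)
    h = resample_profile(ang, d)
    return EdgeProfile(h=h, centroid=np.asarray(centroid, dtype=float), label=label)


# --------------------------------------------------------------------------
# Grain-level correspondence
# --------------------------------------------------------------------------

def _photo_centroids(regions: list[GrainRegion], cam: CameraModel) -> np.ndarray:
    rc = np.array([r.centroid for r in regions])
    return cam.undistort_points(cam.photo_from_raster(rc))


def match_grains(
    left_regions: list[GrainRegion],
    right_regions: list[GrainRegion],
    left_cam: CameraModel,
    right_cam: CameraModel,
    *,
    max_distance: float | None = None,
) -> list[GrainMatch]:
    """One-to-one pairing of grains across the stereo pair.

    For each right-image grain the centroid ray is intersected with the
    board plane and the resulting object point projected into the left
    image; the nearest left centroid within ``max_distance`` px claims the
    pair.  Conflicts are resolved greedily in favour of the smaller
    distance.  ``max_distance`` defaults to half the minimum inter-centroid
    distance in the left image.  Unmatched grains are simply absent from
    the result.
    """
    if not left_regions or not right_regions:
        return []
    left_xy = _photo_centroids(left_regions, left_cam)
    right_xy = _photo_centroids(right_regions, right_cam)
    ground = right_cam.back_project_to_plane(right_xy, z=0.0)
    predicted = left_cam.project(ground)
    if predicted.ndim == 1:
        predicted = predicted[None, :]
    if max_distance is None:
        if len(left_xy) >= 2:
            diff = left_xy[:, None, :] - left_xy[None, :, :]
            dd = np.hypot(diff[..., 0], diff[..., 1])
            np.fill_diagonal(dd, np.inf)
            max_distance = 0.5 * float(dd.min())
        else:
            max_distance = np.inf
    diff = predicted[:, None, :] - left_xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])  # (n_right, n_left)
    cand = np.argwhere(dist <= max_distance)
    order = np.argsort(dist[cand[:, 0], cand[:, 1]], kind="stable")
    used_r: set[int] = set()
    used_l: set[int] = set()
    matches: list[GrainMatch] = []
    for ri, li in cand[order]:
        if ri in used_r or li in used_l:
            continue
        used_r.add(int(ri))
        used_l.add(int(li))
        matches.append(
            GrainMatch(
                left_id=left_regions[li].label,
                right_id=right_regions[ri].label,
                projected_distance=float(dist[ri, li]),
            )
        )
    matches.sort(key=lambda m: (m.left_id, m.right_id))
    return matches


# --------------------------------------------------------------------------
# Edge-point correspondence
# --------------------------------------------------------------------------

def match_edge_points(left: EdgeProfile, right: EdgeProfile) -> EdgeCorrespondence:
    """Best circular alignment of two polar signatures.

    Evaluates the Pearson correlation coefficient between the left profile
    and the right profile rotated by every shift k in 0..359 (computed in
    one pass via the circular cross-correlation theorem) and returns the
    argmax.  Zero-variance profiles are flagged degenerate with shift 0.
    """
    hl = left.h - left.h.mean()
    hr = right.h - right.h.mean()
    sl = float(np.sqrt(np.mean(hl**2)))
    sr = float(np.sqrt(np.mean(hr**2)))
    scale = max(left.h.mean(), right.h.mean(), 1.0)
    if sl < 1e-9 * scale or sr < 1e-9 * scale:
        return EdgeCorrespondence(shift=0, correlation=0.0, degenerate=True)
    # c[k] = sum_i hl[i] * hr[i + k]
    c = np.fft.ifft(np.conj(np.fft.fft(hl)) * np.fft.fft(hr)).real
    corr = c / (N_ANGLES * sl * sr)
    # deterministic tie-break: smallest shift among numerically tied maxima
    k = int(np.nonzero(corr >= corr.max() - 1e-9)[0][0])
    return EdgeCorrespondence(shift=k, correlation=float(corr[k]))


def candidate_shifts(
    left: EdgeProfile, right: EdgeProfile, *, margin: float = 0.02, max_candidates: int = 4
) -> list[EdgeCorrespondence]:
    """Circular-correlation local maxima within ``margin`` of the global one.

    A silhouette with an n-fold symmetry (an ellipse is nearly 2-fold
    symmetric) produces several near-tied alignment peaks that shape alone
    cannot distinguish; callers disambiguate geometrically (the stereo
    reprojection residual of the reconstructed points).  Candidates are
    sorted by descending correlation; the first equals
    :func:`match_edge_points`.
    """
    best = match_edge_points(left, right)
    if best.degenerate:
        return [best]
    hl = left.h - left.h.mean()
    hr = right.h - right.h.mean()
    c = np.fft.ifft(np.conj(np.fft.fft(hl)) * np.fft.fft(hr)).real
    corr = c / (N_ANGLES * np.sqrt(np.mean(hl**2)) * np.sqrt(np.mean(hr**2)))
    peaks = (corr >= np.roll(corr, 1)) & (corr > np.roll(corr, -1))
    peaks &= corr >= best.correlation - margin
    ks = np.nonzero(peaks)[0]
    ks = ks[np.argsort(corr[ks])[::-1]][:max_candidates]
    out = [EdgeCorrespondence(shift=int(k), correlation=float(corr[k])) for k in ks]
    if not out or out[0].shift != best.shift:
        out = [best] + [c_ for c_ in out if c_.shift != best.shift]
    return out


def correspondence_to_image_points(
    corr: EdgeCorrespondence, left: EdgeProfile, right: EdgeProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Matched angles back to photo coordinates: point = centroid + h * (cos, sin).

    Returns two (360, 2) arrays of paired sub-pixel photo points.
    """
    pairs = corr.pairs()
    ang_l = np.radians(pairs[:, 0].astype(float))
    ang_r = np.radians(pairs[:, 1].astype(float))
    hl = left.h[pairs[:, 0]]
    hr = right.h[pairs[:, 1]]
    left_pts = left.centroid + np.column_stack([hl * np.cos(ang_l), hl * np.sin(ang_l)])
    right_pts = right.centroid + np.column_stack([hr * np.cos(ang_r), hr * np.sin(ang_r)])
    return left_pts, right_pts
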