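"""Grain silhouette extraction from a single image.

Pipeline: weighted-sum graying, median denoising, Otsu binarisation, and
connected-component cleanup that discards components with implausibly small
area (broken kernels) or large area (clumped grains).  Each surviving region
carries its binary centroid and an ordered closed boundary from
Moore-neighbour tracing, counter-clockwise in the photo frame (x right,
y up), which downstream polar-profile matching relies on.

Holes are filled before tracing — grains are treated as solid silhouettes —
and the centroid is the unweighted mean of member pixels because all
downstream matching operates on the binarised mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import ConfigError, SegmentationError

__all__ = [
    "GrainRegion",
    "to_gray",
    "median_denoise",
    "otsu_binarize",
    "filter_by_area",
    "trace_boundary",
    "region_centroid",
    "segment_grains",
]

#: ITU-R 601 luma weights used for the weighted-sum graying.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class GrainRegion:
    """One segmented grain.

    ``centroid`` is sub-pixel (row, col); ``boundary`` is a (K, 2) integer
    array of (row, col) boundary pixels, ordered counter-clockwise in the
    photo frame and closed in the sense that the last pixel is 8-adjacent to
    the first.
    """

    label: int
    area: int
    centroid: np.ndarray
    boundary: np.ndarray


def to_gray(image: np.ndarray) -> np.ndarray:
    """Weighted-sum graying 0.2989 R + 0.5870 G + 0.1140 B.

    Single-channel input passes through (as float).  Any channel count other
    than 1 or 3 is an error.
    """
    a = np.asarray(image)
    if a.ndim == 2:
        return a.astype(float)
    if a.ndim == 3 and a.shape[-1] == 1:
        return a[..., 0].astype(float)
    if a.ndim == 3 and a.shape[-1] == 3:
        w = np.asarray(GRAY_WEIGHTS)
        return a.astype(float) @ w
    raise ConfigError(f"expected 1- or 3-channel image, got shape {a.shape}")


def median_denoise(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with a kernel x kernel window and edge-replicated padding."""
    if kernel % 2 == 0 or kernel < 3:
        raise ConfigError(f"median kernel must be odd and >= 3, got {kernel}")
    return ndimage.median_filter(np.asarray(image), size=kernel, mode="nearest")


def otsu_binarize(image: np.ndarray, polarity: str = "bright") -> tuple[np.ndarray, float]:
    """Otsu threshold maximising between-class variance.

    Returns (binary image with foreground == 1, threshold).  ``polarity``
    states whether the target is brighter or darker than the background.
    """
    gray = np.asarray(image)
    flat = gray.ravel()
    if np.all(flat == flat[0]):
        raise SegmentationError("constant image has no threshold")
    if polarity not in ("bright", "dark"):
        raise ConfigError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    thr = float(threshold_otsu(gray))
    binary = gray > thr if polarity == "bright" else gray < thr
    return binary.astype(np.uint8), thr


def _auto_area_limits(areas: np.ndarray) -> tuple[float, float]:
    """Self-scaling defaults: [0.2, 3.0] x the median component area."""
    med = float(np.median(areas))
    return 0.2 * med, 3.0 * med


def filter_by_area(
    binary: np.ndarray,
    min_area: float | None = None,
    max_area: float | None = None,
    *,
    exclude_mask: np.ndarray | None = None,
    drop_border: bool = False,
) -> list[GrainRegion]:
    """Label 8-connected components and keep those within the area limits.

    With ``min_area``/``max_area`` unset, limits default to [0.2, 3.0] x the
    median component area of the image (explicit limits override).
    ``exclude_mask`` removes components overlapping it (e.g. board circles)
    before the area statistics are computed; ``drop_border`` removes
    components touching the image border, whose silhouettes are truncated.
    An empty result is allowed.
    """
    b = np.asarray(binary).astype(bool)
    labels = measure.label(b, connectivity=2)
    n = labels.max()
    if n == 0:
        return []
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    if exclude_mask is not None:
        bad = np.unique(labels[np.asarray(exclude_mask, dtype=bool)])
        keep[bad] = False
    if drop_border:
        edge = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[edge] = False
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    cand = np.nonzero(keep)[0]
    if len(cand) == 0:
        return []
    lo, hi = _auto_area_limits(areas[cand])
    if min_area is not None:
        lo = float(min_area)
    if max_area is not None:
        hi = float(max_area)

    regions: list[GrainRegion] = []
    slices = ndimage.find_objects(labels)
    for lab in cand:
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        comp = ndimage.binary_fill_holes(comp)
        area = int(comp.sum())
        if not (lo <= area <= hi):
            continue
        if area < 5:
            continue
        r0, c0 = sl[0].start, sl[1].start
        rows, cols = np.nonzero(comp)
        centroid = np.array([rows.mean() + r0, cols.mean() + c0])
        boundary = trace_boundary(comp)
        boundary = boundary + np.array([r0, c0])
        regions.append(
            GrainRegion(label=int(lab), area=area, centroid=centroid, boundary=boundary)
        )
    return regions


# Moore neighbourhood in clockwise raster order starting at W; clockwise in
# raster display (row down) is counter-clockwise in the photo frame (y up).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of a single filled component (Moore tracing).

    Returns a (K, 2) integer array of (row, col) boundary pixels with no
    repeats; the last pixel is 8-adjacent to the first.  Orientation is
    counter-clockwise in the photo frame (signed area positive with
    x = col, y = -row).  Components smaller than 5 px are rejected.
    """
    m = np.asarray(mask).astype(bool)
    if m.sum() < 5:
        raise SegmentationError(f"component of area {int(m.sum())} px is too small to trace")
    padded = np.pad(m, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost: W and N free

    def neighbors_from(p, prev):
        dr, dc = prev[0] - p[0], prev[1] - p[1]
        k0 = _MOORE.index((dr, dc))
        for t in range(1, 9):
            dr, dc = _MOORE[(k0 + t) % 8]
            yield (p[0] + dr, p[1] + dc)

    contour = [start]
    prev = (start[0], start[1] - 1)  # backtrack: W neighbour, guaranteed background
    first_entry = None
    p = start
    while True:
        nxt = None
        before = prev
        for q in neighbors_from(p, prev):
            if padded[q]:
                nxt = q
                break
            before = q
        if nxt is None:  # isolated pixel (cannot happen for area >= 5)
            break
        if nxt == start:
            entry = before
            if first_entry is None:
                first_entry = entry
            elif entry == first_entry:
                break
            # fall through: start revisited from a different side (thin limbs)
        prev = before
        p = nxt
        if p == start and first_entry is not None and prev == first_entry:
            break
        if p != start:
            if not contour or contour[-1] != p:
                contour.append(p)
        if len(contour) > 8 * m.sum():  # safety against pathological loops
            break

    out = np.array(contour, dtype=int) - 1  # undo padding
    # de-duplicate while preserving order (thin structures revisit pixels)
    _, idx = np.unique(out, axis=0, return_index=True)
    if len(idx) != len(out):
        out = out[np.sort(idx)]
    # enforce CCW in the photo frame
    x = out[:, 1].astype(float)
    y = -out[:, 0].astype(float)
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if area2 < 0:
        out = out[::-1]
    return out


def region_centroid(region) -> np.ndarray:
    """Unweighted (binary) centroid, as sub-pixel (row, col).

    Accepts a boolean mask or an (N, 2) array of pixel coordinates.
    """
    a = np.asarray(region)
    if a.ndim == 2 and a.dtype != bool and a.shape[1] == 2:
        pts = a.astype(float)
    else:
        rows, cols = np.nonzero(a.astype(bool))
        if len(rows) == 0:
            raise SegmentationError("empty region has no centroid")
        pts = np.column_stack([rows, cols]).astype(float)
    return pts.mean(axis=0)


def segment_grains(
    image: np.ndarray,
    *,
    median_kernel: int = 3,
    min_area: float | None = None,
    max_area: float | None = None,
    polarity: str = "bright",
    exclude_mask: np.ndarray | None = None,
    drop_border: bool = True,
) -> list[GrainRegion]:
    """Full single-image pipeline: gray -> median -> Otsu -> area filter.

    ``exclude_mask`` (typically the detected board-circle components) removes
    non-grain bright objects before grain statistics are computed.
    Deterministic: identical input bytes yield identical regions.
    """
    gray = to_gray(image)
    den = median_denoise(gray, median_kernel)
    binary, _ = otsu_binarize(den, polarity)
    return filter_by_area(
        binary,
        min_area,
        max_area,
        exclude_mask=exclude_mask,
        drop_border=drop_border,
    )
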