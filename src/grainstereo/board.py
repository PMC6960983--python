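"""Calibration-board control points.

The background board carries a regular grid of circles with known radius and
spacing.  The object-space frame has its origin at the centre of the
upper-left circle, X along the long side of the board (grid columns), Y along
the short side (grid rows) and Z perpendicular to the board, so every circle
centre is a control point at (j * spacing_x, i * spacing_y, 0).

Detection is centroid-based: Otsu threshold, connected components filtered to
round blobs of plausible area, then an intensity-weighted sub-pixel centroid
per circle.  Ordering assumes the board appears roughly upright in the photo
frame (board +X within 45 degrees of photo +x), which holds for any
near-nadir camera with small in-plane rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import ConfigError, InsufficientControlError, OrderingError
from .segmentation import to_gray

__all__ = [
    "BoardLayout",
    "ControlPoint",
    "board_object_coordinates",
    "board_grid_indices",
    "detect_circle_centers",
    "order_control_points",
    "load_board",
    "save_board",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoardLayout:
    """Circle-grid geometry: dimensions, centre spacing (mm) and radius (mm)."""

    n_rows: int
    n_cols: int
    spacing_x: float
    spacing_y: float
    radius: float
    polarity: str = "bright"  # circles bright on a dark board, or "dark"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ConfigError("board grid must be at least 2 x 2")
        if min(self.spacing_x, self.spacing_y) <= 2.0 * self.radius:
            raise ConfigError("circle spacing must exceed the circle diameter")
        if self.polarity not in ("bright", "dark"):
            raise ConfigError(f"polarity must be 'bright' or 'dark', got {self.polarity!r}")

    @property
    def n_circles(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class ControlPoint:
    """One board circle: object coordinates (Z=0), photo coordinates, grid cell."""

    object: np.ndarray   # (3,) mm, Z == 0
    image: np.ndarray    # (2,) photo coordinates, px
    grid_index: tuple[int, int]


def board_grid_indices(layout: BoardLayout) -> np.ndarray:
    """(N, 2) array of (row i, col j) grid indices in row-major order."""
    i, j = np.mgrid[0 : layout.n_rows, 0 : layout.n_cols]
    return np.column_stack([i.ravel(), j.ravel()])


def board_object_coordinates(layout: BoardLayout) -> np.ndarray:
    """(N, 3) object coordinates of all circle centres, row-major over (i, j)."""
    ij = board_grid_indices(layout)
    return np.column_stack(
        [ij[:, 1] * layout.spacing_x, ij[:, 0] * layout.spacing_y, np.zeros(len(ij))]
    )


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_circle_centers(
    image: np.ndarray,
    layout: BoardLayout,
    *,
    return_mask: bool = False,
):
    """Sub-pixel centroids of the board circles, as (row, col) raster coordinates.

    Otsu-thresholds the image with the layout's polarity, keeps connected
    components that are round (low eccentricity, high solidity) with area in
    [0.5, 2.0] x the median candidate area, and returns the intensity-weighted
    centroid of each.  With ``return_mask=True`` also returns a boolean mask
    of the accepted circle components, which downstream segmentation uses to
    exclude circles from grain candidates.

    Raises :class:`InsufficientControlError` if fewer than 4 circles are found.
    """
    gray = to_gray(np.asarray(image))
    flat = gray.ravel()
    if np.all(flat == flat[0]):
        raise InsufficientControlError("blank image: no circles detectable")
    thr = threshold_otsu(gray)
    binary = gray > thr if layout.polarity == "bright" else gray < thr
    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels)
    candidates = [
        p for p in props
        if p.area >= 20 and p.eccentricity < 0.6 and p.solidity > 0.85
    ]
    if len(candidates) >= 1:
        med_area = float(np.median([p.area for p in candidates]))
        candidates = [p for p in candidates if 0.5 * med_area <= p.area <= 2.0 * med_area]
    if len(candidates) < 4:
        raise InsufficientControlError(
            f"only {len(candidates)} board circles detected (need >= 4)"
        )
    if len(candidates) > layout.n_circles:
        # keep the roundest n_circles blobs
        candidates.sort(key=lambda p: p.eccentricity)
        candidates = candidates[: layout.n_circles]

    background = float(np.median(gray[~binary])) if (~binary).any() else 0.0
    weights_img = gray - background if layout.polarity == "bright" else background - gray
    centers = np.empty((len(candidates), 2))
    mask = np.zeros(gray.shape, dtype=bool)
    for idx, p in enumerate(candidates):
        comp = labels == p.label
        mask |= comp
        # dilate so anti-aliased rim pixels contribute to the centroid
        foot = ndimage.binary_dilation(comp, iterations=2)
        w = np.clip(weights_img, 0.0, None) * foot
        total = w.sum()
        rows, cols = np.nonzero(foot)
        wv = w[rows, cols]
        centers[idx] = [(rows * wv).sum() / total, (cols * wv).sum() / total]
    if return_mask:
        return centers, mask
    return centers


# --------------------------------------------------------------------------
# Ordering
# --------------------------------------------------------------------------

def _split_by_gaps(values: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign each value to one of ``n_groups`` 1-D clusters.

    Sorts and cuts at the (n_groups - 1) largest gaps — robust for grid
    projections where within-group scatter is far below the grid pitch.
    Returns a group id per input value, groups numbered in ascending order.
    """
    order = np.argsort(values)
    sorted_v = values[order]
    gaps = np.diff(sorted_v)
    if n_groups > 1:
        cut_idx = np.sort(np.argsort(gaps)[-(n_groups - 1):])
    else:
        cut_idx = np.array([], dtype=int)
    group_sorted = np.zeros(len(values), dtype=int)
    for c in cut_idx:
        group_sorted[c + 1:] += 1
    groups = np.empty(len(values), dtype=int)
    groups[order] = group_sorted
    return groups


def order_control_points(detected, layout: BoardLayout) -> list[ControlPoint]:
    """Pair detected circle centres (photo coordinates) with board cells.

    Input points must already be in photo coordinates (x right, y up) and,
    if the lens distorts, undistorted.  Row index i follows ascending photo
    y (board +Y maps to photo +y for any attitude with |kappa| < 45 deg);
    column index j follows ascending photo x.  Missing circles are allowed
    (they simply leave gaps in the grid); two detections claiming the same
    cell raise :class:`OrderingError`.
    """
    pts = np.asarray(detected, dtype=float).reshape(-1, 2)
    if len(pts) < 4:
        raise InsufficientControlError(f"cannot order {len(pts)} control points (need >= 4)")
    if len(pts) > layout.n_circles:
        raise OrderingError(
            f"{len(pts)} detections exceed the {layout.n_circles}-circle grid"
        )
    rows = _split_by_gaps(pts[:, 1], layout.n_rows)
    cols = _split_by_gaps(pts[:, 0], layout.n_cols)
    seen: dict[tuple[int, int], int] = {}
    out: list[ControlPoint] = []
    for k, (i, j) in enumerate(zip(rows, cols)):
        cell = (int(i), int(j))
        if cell in seen:
            raise OrderingError(f"two detections map to board cell {cell}")
        seen[cell] = k
        obj = np.array([cell[1] * layout.spacing_x, cell[0] * layout.spacing_y, 0.0])
        out.append(ControlPoint(object=obj, image=pts[k].copy(), grid_index=cell))
    missing = layout.n_circles - len(out)
    if missing:
        have = set(seen)
        lost = [
            (i, j)
            for i in range(layout.n_rows)
            for j in range(layout.n_cols)
            if (i, j) not in have
        ]
        log.info("board cells without a detection: %s", lost)
    out.sort(key=lambda c: c.grid_index)
    return out


# --------------------------------------------------------------------------
# Config I/O
# --------------------------------------------------------------------------

def board_from_dict(d: dict) -> BoardLayout:
    try:
        return BoardLayout(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            spacing_x=float(d["spacing_x_mm"]),
            spacing_y=float(d["spacing_y_mm"]),
            radius=float(d["radius_mm"]),
            polarity=str(d.get("polarity", "bright")),
        )
    except KeyError as exc:
        raise ConfigError(f"board layout missing key: {exc}") from exc


def board_to_dict(layout: BoardLayout) -> dict:
    return {
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "spacing_x_mm": layout.spacing_x,
        "spacing_y_mm": layout.spacing_y,
        "radius_mm": layout.radius,
        "polarity": layout.polarity,
    }


def load_board(path) -> BoardLayout:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"board layout {path} is not a mapping")
    return board_from_dict(data)


def save_board(layout: BoardLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(board_to_dict(layout), fh, sort_keys=False)
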