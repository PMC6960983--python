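"""Edge-height reconstruction and the half-thickness estimator.

A grain resting on the board shows its occluding rim at height h above the
board when one side faces up and at H - h when flipped, H being the grain
thickness.  With fair random flips the expected rim height is H / 2, so the
population thickness is estimated as twice the mean rim height:

    H_hat = 2 * mean over grains of (mean over edge points of Z)

The per-grain mean is taken first and then averaged over grains (pooling all
points instead would weight grains by boundary length).  Reconstructed
heights are signed Z values in the board frame; negative values are kept so
the noise distribution stays unbiased.  An optional reprojection-residual
cap can drop grossly mismatched point pairs (off by default: the plain mean
is the reference behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edges import GrainMatch
from .errors import ConfigError
from .geometry import CameraModel, intersect_many

__all__ = ["GrainHeightResult", "ThicknessReport", "reconstruct_edge_heights", "aggregate_thickness"]


@dataclass
class GrainHeightResult:
    """Edge heights of one matched grain pair.

    ``edge_height`` is the arithmetic mean of the surviving point heights;
    ``mean_residual`` the mean RMS reprojection residual (px).
    """

    grain_pair: GrainMatch | None
    point_heights: np.ndarray
    edge_height: float
    mean_residual: float
    n_points_used: int
    n_points_total: int


@dataclass
class ThicknessReport:
    """Population thickness: 2 x mean over grains of the per-grain edge height."""

    n_grains: int
    per_grain: list[GrainHeightResult]
    thickness: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.per_grain:
            rows.append(
                {
                    "left_id": g.grain_pair.left_id if g.grain_pair else -1,
                    "right_id": g.grain_pair.right_id if g.grain_pair else -1,
                    "n_points_used": g.n_points_used,
                    "edge_height_mm": g.edge_height,
                    "residual_px": g.mean_residual,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Per-grain rows plus a summary row (n_grains, thickness)."""
        frame = self.to_frame()
        summary = pd.DataFrame(
            [
                {
                    "left_id": "summary",
                    "right_id": "",
                    "n_points_used": int(sum(g.n_points_used for g in self.per_grain)),
                    "edge_height_mm": self.thickness / 2.0,
                    "residual_px": float(np.mean([g.mean_residual for g in self.per_grain])),
                    "n_grains": self.n_grains,
                    "thickness_mm": self.thickness,
                }
            ]
        )
        pd.concat([frame, summary], ignore_index=True).to_csv(path, index=False)


def reconstruct_edge_heights(
    left_points,
    right_points,
    left_cam: CameraModel,
    right_cam: CameraModel,
    *,
    residual_cap: float | None = None,
    grain_pair: GrainMatch | None = None,
) -> GrainHeightResult:
    """Space-intersect every matched edge-point pair and average the heights.

    ``residual_cap`` (px), when set, drops pairs whose RMS reprojection
    residual exceeds it; raises :class:`ConfigError` if that leaves nothing.
    """
    lp = np.asarray(left_points, dtype=float).reshape(-1, 2)
    rp = np.asarray(right_points, dtype=float).reshape(-1, 2)
    if len(lp) == 0 or len(lp) != len(rp):
        raise ConfigError("need equal, nonzero numbers of left/right edge points")
    pts, rms = intersect_many(lp, rp, left_cam, right_cam)
    heights = pts[:, 2]
    total = len(heights)
    if residual_cap is not None:
        keep = rms <= residual_cap
        if not keep.any():
            raise ConfigError("residual cap dropped every edge point")
        heights, rms = heights[keep], rms[keep]
    return GrainHeightResult(
        grain_pair=grain_pair,
        point_heights=heights,
        edge_height=float(heights.mean()),
        mean_residual=float(rms.mean()),
        n_points_used=len(heights),
        n_points_total=total,
    )


def aggregate_thickness(results: list[GrainHeightResult]) -> ThicknessReport:
    """Thickness = 2 x mean over grains of the per-grain edge height."""
    if not results:
        raise ConfigError("cannot aggregate thickness of zero grains")
    mean_edge = float(np.mean([g.edge_height for g in results]))
    return ThicknessReport(
        n_grains=len(results), per_grain=list(results), thickness=2.0 * mean_edge
    )
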