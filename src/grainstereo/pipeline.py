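"""Workflow wiring: orientation and full stereo measurement.

The measurement flow mirrors the field procedure: undistort observations,
segment grains in both images (board circles excluded), match corresponding
grains by object-space projection, match corresponding edge points by polar
signature correlation, space-intersect every matched pair and convert the
mean edge height into thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .board import BoardLayout, detect_circle_centers, order_control_points
from .edges import (
    EdgeCorrespondence,
    GrainMatch,
    candidate_shifts,
    correspondence_to_image_points,
    match_grains,
    profile_from_boundary,
)
from .errors import ConfigError
from .geometry import CameraModel, ResectionResult, space_resection
from .segmentation import GrainRegion, segment_grains
from .thickness import GrainHeightResult, ThicknessReport, aggregate_thickness, reconstruct_edge_heights

__all__ = ["PipelineConfig", "MeasurementResult", "orient_camera", "measure_pair", "save_match_overlay"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable measurement parameters (documented defaults, all overridable)."""

    median_kernel: int = 3
    min_area: float | None = None
    max_area: float | None = None
    polarity: str = "bright"
    max_match_distance: float | None = None   # px; default: half min left spacing
    residual_cap: float | None = None         # px; None = keep all edge points
    min_correlation: float | None = None      # drop grain pairs below this, if set


@dataclass
class GrainPairDetail:
    """One matched grain pair with its edge correspondence and image points."""

    match: GrainMatch
    correspondence: EdgeCorrespondence
    left_points: np.ndarray    # (360, 2) photo coords
    right_points: np.ndarray
    heights: GrainHeightResult


@dataclass
class MeasurementResult:
    report: ThicknessReport
    matches: list[GrainMatch]
    details: list[GrainPairDetail]
    n_left_regions: int
    n_right_regions: int

    def correspondences_frame(self) -> pd.DataFrame:
        """All matched edge points: one row per (grain pair, angle pair)."""
        rows = []
        for d in self.details:
            pairs = d.correspondence.pairs()
            for (ai, aj), (xl, yl), (xr, yr) in zip(pairs, d.left_points, d.right_points):
                rows.append(
                    {
                        "left_id": d.match.left_id,
                        "right_id": d.match.right_id,
                        "angle_left": int(ai),
                        "angle_right": int(aj),
                        "x_l": xl, "y_l": yl, "x_r": xr, "y_r": yr,
                    }
                )
        return pd.DataFrame(rows)


def orient_camera(
    image: np.ndarray,
    layout: BoardLayout,
    camera: CameraModel,
    *,
    initial=None,
) -> tuple[CameraModel, ResectionResult]:
    """Recover a camera's exterior orientation from the board in its image.

    Detects circle centres, converts them to undistorted photo coordinates,
    orders them against the board grid and runs space resection.
    """
    cam = camera
    if cam.image_size is None:
        h, w = np.asarray(image).shape[:2]
        cam = CameraModel(cam.io, cam.eo, cam.distortion, (w, h))
    centers = detect_circle_centers(image, layout)
    photo = cam.undistort_points(cam.photo_from_raster(centers))
    control = order_control_points(photo, layout)
    result = space_resection(control, cam.io, initial)
    log.info("resection: %d control points, RMS %.4f px", result.n_points, result.rms)
    return cam.with_eo(result.eo), result


def _grain_profiles(regions: list[GrainRegion], cam: CameraModel):
    profiles = {}
    for r in regions:
        boundary = cam.undistort_points(cam.photo_from_raster(r.boundary.astype(float)))
        centroid = cam.undistort_points(cam.photo_from_raster(r.centroid))
        profiles[r.label] = profile_from_boundary(boundary, centroid, label=r.label)
    return profiles


def measure_pair(
    left_image: np.ndarray,
    right_image: np.ndarray,
    left_cam: CameraModel,
    right_cam: CameraModel,
    layout: BoardLayout,
    config: PipelineConfig | None = None,
) -> MeasurementResult:
    """Run the full thickness measurement on one oriented stereo pair."""
    cfg = config or PipelineConfig()
    if left_cam.eo is None or right_cam.eo is None:
        raise ConfigError("both cameras must be oriented before measurement")

    regions = {}
    for side, img in (("left", left_image), ("right", right_image)):
        _, circle_mask = detect_circle_centers(img, layout, return_mask=True)
        regions[side] = segment_grains(
            img,
            median_kernel=cfg.median_kernel,
            min_area=cfg.min_area,
            max_area=cfg.max_area,
            polarity=cfg.polarity,
            exclude_mask=circle_mask,
        )
    left_regions, right_regions = regions["left"], regions["right"]
    matches = match_grains(
        left_regions, right_regions, left_cam, right_cam,
        max_distance=cfg.max_match_distance,
    )
    left_prof = _grain_profiles(left_regions, left_cam)
    right_prof = _grain_profiles(right_regions, right_cam)

    details: list[GrainPairDetail] = []
    results: list[GrainHeightResult] = []
    for m in matches:
        lp, rp = left_prof[m.left_id], right_prof[m.right_id]
        candidates = candidate_shifts(lp, rp)
        if candidates[0].degenerate:
            log.warning("degenerate edge profile for pair %s; skipped", m)
            continue
        if (
            cfg.min_correlation is not None
            and candidates[0].correlation < cfg.min_correlation
        ):
            log.info("pair %s dropped: correlation %.3f", m, candidates[0].correlation)
            continue
        # near-tied shape alignments (symmetric silhouettes) are broken by
        # stereo consistency: keep the shift with the smallest residual
        best = None
        for corr in candidates:
            lpts, rpts = correspondence_to_image_points(corr, lp, rp)
            heights = reconstruct_edge_heights(
                lpts, rpts, left_cam, right_cam,
                residual_cap=cfg.residual_cap, grain_pair=m,
            )
            if best is None or heights.mean_residual < best[2].mean_residual:
                best = (corr, (lpts, rpts), heights)
        corr, (lpts, rpts), heights = best
        results.append(heights)
        details.append(GrainPairDetail(m, corr, lpts, rpts, heights))
    report = aggregate_thickness(results)
    return MeasurementResult(
        report=report,
        matches=matches,
        details=details,
        n_left_regions=len(left_regions),
        n_right_regions=len(right_regions),
    )


def save_match_overlay(
    left_image: np.ndarray,
    right_image: np.ndarray,
    result: MeasurementResult,
    left_cam: CameraModel,
    right_cam: CameraModel,
    path,
    *,
    every_deg: int = 20,
) -> None:
    """Debug visualisation: matched edge points joined across the two views."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import ConnectionPatch

    fig, axes = plt.subplots(1, 2, figsize=(14, 6))
    for ax, img, title in zip(axes, (left_image, right_image), ("left", "right")):
        ax.imshow(img, cmap="gray", interpolation="nearest")
        ax.set_title(title)
        ax.set_axis_off()
    for d in result.details:
        sel = slice(0, None, every_deg)
        lrc = left_cam.raster_from_photo(left_cam.distort_points(d.left_points[sel]))
        rrc = right_cam.raster_from_photo(right_cam.distort_points(d.right_points[sel]))
        axes[0].plot(lrc[:, 1], lrc[:, 0], ".", ms=2, color="yellow")
        axes[1].plot(rrc[:, 1], rrc[:, 0], ".", ms=2, color="yellow")
        for (rl, cl), (rr, cr) in zip(lrc, rrc):
            fig.add_artist(
                ConnectionPatch(
                    xyA=(cl, rl), coordsA=axes[0].transData,
                    xyB=(cr, rr), coordsB=axes[1].transData,
                    lw=0.3, color="yellow", alpha=0.5,
                )
            )
    fig.savefig(path, dpi=110)
    plt.close(fig)
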