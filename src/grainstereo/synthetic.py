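"""Ground-truthed synthetic stereo scenes.

Emulates the measurement setup: convex grains of known thickness H scattered
and randomly flipped on a calibration board in the Z = 0 plane, imaged by two
near-nadir pinhole cameras about 350 mm above the board with a configurable
baseline (default 80 mm, base-height ratio ~0.23) at an image scale of about
0.1 mm per pixel.

Each grain's occluding rim is modelled as the planar ellipse with semi-axes
(a, b) at the rim height H/2 + delta or H/2 - delta depending on which side
faces up; delta is the rim-plane offset of an asymmetric grain and is the
sole source of per-grain edge-height variance that population averaging
cancels.  The silhouette is the perspective projection of that rim curve —
analytic, so the ground truth is exact.  Self-occlusion of a full 3D solid
is deliberately not modelled (valid near nadir).

``rim_inset_px`` emulates the systematic under-segmentation of translucent
grain edges: the rendered contour is inset by that many pixels in planform
and lifted onto the grain's upper surface (modelled as a half-ellipsoid with
vertical semi-axis H - rim_height), which rises inward — the mechanism that
biases measured thickness upward on real imagery.

Rendering is anti-aliased (sub-pixel polygon coverage), followed by optional
Gaussian blur and additive Gaussian gray noise; every random choice is
driven by an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from matplotlib.path import Path
from scipy import ndimage

from .board import BoardLayout, board_object_coordinates, board_from_dict, board_to_dict
from .errors import ConfigError, PackingError
from .geometry import (
    CameraModel,
    ExteriorOrientation,
    InteriorOrientation,
    camera_from_dict,
    camera_to_dict,
)

__all__ = [
    "GrainParams",
    "GrainTruth",
    "RigParams",
    "SceneTruth",
    "default_board",
    "make_rig",
    "sample_scene",
    "render_stereo",
    "simulate_rim_heights",
    "evaluate_scene",
    "evaluate_pipeline",
    "sweep_sample_size",
    "sweep_baseline",
    "SceneEvaluation",
]


@dataclass(frozen=True)
class GrainParams:
    """Population parameters of the simulated grains (mm).

    Semi-axes a > b describe the elongated silhouette; H is the thickness
    and delta the rim-plane offset from mid-height.  Small uniform jitter on
    the semi-axes keeps silhouettes from being identical.
    """

    a: float = 3.5
    b: float = 1.1
    a_jitter: float = 0.25
    b_jitter: float = 0.1
    H: float = 1.8
    delta: float = 0.15

    def __post_init__(self) -> None:
        if not (self.a > self.b > 0):
            raise ConfigError("grain semi-axes must satisfy a > b > 0")
        if not (0 <= self.delta < self.H / 2):
            raise ConfigError("rim offset must satisfy 0 <= delta < H/2")


@dataclass(frozen=True)
class GrainTruth:
    """One simulated grain: silhouette, pose, flip state and true heights."""

    a: float
    b: float
    H: float
    delta: float
    x: float
    y: float
    yaw: float
    flip: bool

    @property
    def rim_height(self) -> float:
        """Height of the occluding rim above the board: H/2 +- delta."""
        return self.H / 2.0 + (self.delta if self.flip else -self.delta)


@dataclass(frozen=True)
class RigParams:
    """Stereo rig: two nadir cameras on an X-parallel baseline.

    ``camera_height`` (mm) and ``pixel_scale`` (mm/px at the board plane)
    fix the principal distance f = camera_height / pixel_scale.  The image
    size is computed so both cameras cover the board plus a margin.
    """

    camera_height: float = 350.0
    baseline: float = 80.0
    pixel_scale: float = 0.1
    margin_mm: float = 6.0
    max_image_px: int = 4096

    @property
    def base_height_ratio(self) -> float:
        return self.baseline / self.camera_height

    @property
    def f(self) -> float:
        return self.camera_height / self.pixel_scale


def default_board() -> BoardLayout:
    return BoardLayout(n_rows=4, n_cols=6, spacing_x=16.0, spacing_y=16.0, radius=2.5)


def make_rig(layout: BoardLayout, rig: RigParams) -> tuple[CameraModel, CameraModel]:
    """Two nadir cameras straddling the board centre along X.

    The common image size is chosen so that the board, expanded by the
    margin, falls inside both fields of view.
    """
    bx = (layout.n_cols - 1) * layout.spacing_x
    by = (layout.n_rows - 1) * layout.spacing_y
    cx, cy = bx / 2.0, by / 2.0
    m = rig.margin_mm
    xs = np.array([cx - rig.baseline / 2.0, cx + rig.baseline / 2.0])
    half_x = max(abs(-m - x) for x in xs)
    half_x = max(half_x, max(abs(bx + m - x) for x in xs))
    half_y = max(abs(-m - cy), abs(by + m - cy))
    width = 2 * int(np.ceil(half_x / rig.pixel_scale)) + 40
    height = 2 * int(np.ceil(half_y / rig.pixel_scale)) + 40
    if max(width, height) > rig.max_image_px:
        raise ConfigError(
            f"required image size {width}x{height} exceeds {rig.max_image_px} px; "
            "reduce the baseline or board extent"
        )
    io = InteriorOrientation(0.0, 0.0, rig.f)
    cams = tuple(
        CameraModel(
            io=io,
            eo=ExteriorOrientation(float(x), cy, rig.camera_height, 0.0, 0.0, 0.0),
            image_size=(width, height),
        )
        for x in xs
    )
    return cams[0], cams[1]


@dataclass
class SceneTruth:
    """Full ground truth of one synthetic stereo scene."""

    grains: list[GrainTruth]
    layout: BoardLayout
    left_cam: CameraModel
    right_cam: CameraModel
    seed: int
    pixel_scale: float
    noise_sigma: float = 2.0
    blur_sigma: float = 0.5
    rim_inset_px: float = 0.0

    @property
    def true_thickness(self) -> float:
        return float(np.mean([g.H for g in self.grains])) if self.grains else float("nan")

    @property
    def true_rim_heights(self) -> np.ndarray:
        return np.array([g.rim_height for g in self.grains])

    # -- JSON bundle -------------------------------------------------------
    def to_json(self, path=None) -> str:
        d = {
            "seed": self.seed,
            "pixel_scale": self.pixel_scale,
            "noise_sigma": self.noise_sigma,
            "blur_sigma": self.blur_sigma,
            "rim_inset_px": self.rim_inset_px,
            "layout": board_to_dict(self.layout),
            "left_cam": camera_to_dict(self.left_cam),
            "right_cam": camera_to_dict(self.right_cam),
            "grains": [asdict(g) for g in self.grains],
        }
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SceneTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            grains=[GrainTruth(**g) for g in d["grains"]],
            layout=board_from_dict(d["layout"]),
            left_cam=camera_from_dict(d["left_cam"]),
            right_cam=camera_from_dict(d["right_cam"]),
            seed=int(d["seed"]),
            pixel_scale=float(d["pixel_scale"]),
            noise_sigma=float(d["noise_sigma"]),
            blur_sigma=float(d["blur_sigma"]),
            rim_inset_px=float(d.get("rim_inset_px", 0.0)),
        )


# --------------------------------------------------------------------------
# Scene sampling
# --------------------------------------------------------------------------

def simulate_rim_heights(n: int, H: float = 1.8, delta: float = 0.2, seed: int = 0) -> np.ndarray:
    """Rim heights of n independently, fairly flipped grains: H/2 +- delta."""
    rng = np.random.default_rng(seed)
    flips = rng.random(n) < 0.5
    return H / 2.0 + np.where(flips, delta, -delta)


def sample_scene(
    n_grains: int = 20,
    grain_params: GrainParams | None = None,
    rig: RigParams | None = None,
    layout: BoardLayout | None = None,
    seed: int = 0,
    *,
    noise_sigma: float = 2.0,
    blur_sigma: float = 0.5,
    rim_inset_px: float = 0.0,
    max_tries_per_grain: int = 2000,
) -> SceneTruth:
    """Randomly seed non-overlapping grains on the board.

    Positions are rejection-sampled so grain silhouettes clear each other
    and the board circles; flips are fair Bernoulli(1/2).  Reproducible for
    a fixed seed; raises :class:`PackingError` when the board cannot hold
    the requested number of grains.
    """
    gp = grain_params or GrainParams()
    rp = rig or RigParams()
    lay = layout or default_board()
    left_cam, right_cam = make_rig(lay, rp)
    rng = np.random.default_rng(seed)

    bx = (lay.n_cols - 1) * lay.spacing_x
    by = (lay.n_rows - 1) * lay.spacing_y
    circles = board_object_coordinates(lay)[:, :2]

    grains: list[GrainTruth] = []
    placed: list[tuple[float, float, float]] = []  # (x, y, a)
    for _ in range(n_grains):
        a = gp.a + rng.uniform(-gp.a_jitter, gp.a_jitter)
        b = gp.b + rng.uniform(-gp.b_jitter, gp.b_jitter)
        yaw = float(rng.uniform(0.0, np.pi))
        flip = bool(rng.random() < 0.5)
        for _try in range(max_tries_per_grain):
            x = float(rng.uniform(0.0, bx))
            y = float(rng.uniform(0.0, by))
            dc = np.hypot(circles[:, 0] - x, circles[:, 1] - y)
            if dc.min() < a + lay.radius + 0.8:
                continue
            ok = all(
                np.hypot(px - x, py - y) >= a + pa + 1.0 for px, py, pa in placed
            )
            if ok:
                break
        else:
            raise PackingError(
                f"could not place grain {len(grains) + 1} of {n_grains} "
                f"after {max_tries_per_grain} tries"
            )
        placed.append((x, y, a))
        grains.append(
            GrainTruth(a=float(a), b=float(b), H=gp.H, delta=gp.delta,
                       x=x, y=y, yaw=yaw, flip=flip)
        )
    return SceneTruth(
        grains=grains,
        layout=lay,
        left_cam=left_cam,
        right_cam=right_cam,
        seed=int(seed),
        pixel_scale=rp.pixel_scale,
        noise_sigma=noise_sigma,
        blur_sigma=blur_sigma,
        rim_inset_px=rim_inset_px,
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_BG_LEVEL = 30.0
_CIRCLE_LEVEL = 200.0
_GRAIN_LEVEL = 225.0
_SUBSAMPLE = 3  # 3x3 sub-pixel coverage grid


def _circle_contour(cx: float, cy: float, radius: float, n: int = 128) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [cx + radius * np.cos(th), cy + radius * np.sin(th), np.zeros(n)]
    )


def grain_rim_contour(
    grain: GrainTruth, inset_mm: float = 0.0, n: int = 256
) -> np.ndarray:
    """3D points of the grain's (possibly inset) rim contour.

    With zero inset this is the planar rim ellipse at the grain's rim
    height.  A positive inset shrinks the planform by ``inset_mm`` and
    lifts each contour point onto the upper surface (half-ellipsoid with
    vertical semi-axis H - rim_height), emulating under-segmentation of
    translucent edges.
    """
    ae = grain.a - inset_mm
    be = grain.b - inset_mm
    if min(ae, be) <= 0.05:
        raise ConfigError("rim inset swallows the grain silhouette")
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    px = ae * np.cos(th)
    py = be * np.sin(th)
    u2 = (px / grain.a) ** 2 + (py / grain.b) ** 2
    lift = (grain.H - grain.rim_height) * np.sqrt(np.clip(1.0 - u2, 0.0, None))
    z = grain.rim_height + lift
    cy_, sy_ = np.cos(grain.yaw), np.sin(grain.yaw)
    X = grain.x + cy_ * px - sy_ * py
    Y = grain.y + sy_ * px + cy_ * py
    return np.column_stack([X, Y, z])


def _paint(canvas: np.ndarray, poly_rc: np.ndarray, value: float) -> None:
    """Anti-aliased fill of a raster polygon by sub-pixel coverage."""
    h, w = canvas.shape
    r_lo = max(int(np.floor(poly_rc[:, 0].min())) - 2, 0)
    r_hi = min(int(np.ceil(poly_rc[:, 0].max())) + 3, h)
    c_lo = max(int(np.floor(poly_rc[:, 1].min())) - 2, 0)
    c_hi = min(int(np.ceil(poly_rc[:, 1].max())) + 3, w)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rows = np.arange(r_lo, r_hi)
    cols = np.arange(c_lo, c_hi)
    offs = (np.arange(_SUBSAMPLE) - (_SUBSAMPLE - 1) / 2.0) / _SUBSAMPLE
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts_r = (rr[..., None, None] + offs[None, None, :, None]).ravel()
    pts_c = (cc[..., None, None] + offs[None, None, None, :]).ravel()
    path = Path(poly_rc[:, ::-1])  # Path expects (x, y) = (col, row)
    inside = path.contains_points(np.column_stack([pts_c, pts_r]))
    cov = inside.reshape(len(rows), len(cols), -1).mean(axis=2)
    patch = canvas[r_lo:r_hi, c_lo:c_hi]
    np.maximum(patch, _BG_LEVEL + (value - _BG_LEVEL) * cov, out=patch)


def _render_view(scene: SceneTruth, cam: CameraModel, noise_rng: np.random.Generator) -> np.ndarray:
    w, h = cam.image_size
    canvas = np.full((h, w), _BG_LEVEL)
    inset_mm = scene.rim_inset_px * scene.pixel_scale
    for cx, cy, _ in board_object_coordinates(scene.layout):
        contour = _circle_contour(cx, cy, scene.layout.radius)
        rc = cam.raster_from_photo(cam.distort_points(cam.project(contour)))
        _paint(canvas, rc, _CIRCLE_LEVEL)
    for grain in scene.grains:
        contour = grain_rim_contour(grain, inset_mm)
        rc = cam.raster_from_photo(cam.distort_points(cam.project(contour)))
        _paint(canvas, rc, _GRAIN_LEVEL)
    if scene.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, scene.blur_sigma)
    if scene.noise_sigma > 0:
        canvas = canvas + noise_rng.normal(0.0, scene.noise_sigma, canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def render_stereo(scene: SceneTruth) -> tuple[np.ndarray, np.ndarray]:
    """Render the scene through both cameras; returns (left, right) uint8 images."""
    left = _render_view(scene, scene.left_cam, np.random.default_rng([scene.seed, 1]))
    right = _render_view(scene, scene.right_cam, np.random.default_rng([scene.seed, 2]))
    return left, right


# --------------------------------------------------------------------------
# End-to-end evaluation
# --------------------------------------------------------------------------

@dataclass
class SceneEvaluation:
    """Full-pipeline result on one rendered scene, against ground truth.

    ``error_mm`` compares against the nominal grain thickness H;
    ``reconstruction_error_mm`` compares against 2 x the mean *realised*
    rim height, isolating geometric pipeline error from the finite-sample
    noise of the random flips.
    """

    thickness_mm: float
    true_thickness_mm: float
    error_mm: float
    reconstruction_error_mm: float
    n_grains_true: int
    n_grains_measured: int
    resection_rms_px: tuple[float, float]
    report: object = field(repr=False, default=None)


def evaluate_scene(scene: SceneTruth, config=None) -> SceneEvaluation:
    """Render the scene and run the full measurement pipeline on it.

    Orientation is recovered by space resection from the rendered board
    (the true exterior orientation is never given to the pipeline).
    """
    from .pipeline import PipelineConfig, measure_pair, orient_camera

    cfg = config or PipelineConfig()
    left_img, right_img = render_stereo(scene)
    blank_left = replace(scene.left_cam, eo=None)
    blank_right = replace(scene.right_cam, eo=None)
    left_cam, res_l = orient_camera(left_img, scene.layout, blank_left)
    right_cam, res_r = orient_camera(right_img, scene.layout, blank_right)
    result = measure_pair(left_img, right_img, left_cam, right_cam, scene.layout, cfg)
    est = result.report.thickness
    truth = scene.true_thickness
    realized = 2.0 * float(scene.true_rim_heights.mean())
    return SceneEvaluation(
        thickness_mm=est,
        true_thickness_mm=truth,
        error_mm=est - truth,
        reconstruction_error_mm=est - realized,
        n_grains_true=len(scene.grains),
        n_grains_measured=result.report.n_grains,
        resection_rms_px=(res_l.rms, res_r.rms),
        report=result.report,
    )


#: Alias matching the workflow vocabulary (render + orient + measure + compare).
evaluate_pipeline = evaluate_scene


def _scene_for(n_grains: int, seed: int, baseline: float | None, **kwargs) -> SceneTruth:
    rig = kwargs.pop("rig", None) or RigParams()
    if baseline is not None:
        rig = replace(rig, baseline=baseline)
    return sample_scene(n_grains=n_grains, rig=rig, seed=seed, **kwargs)


def sweep_sample_size(
    sample_sizes=(2, 5, 10, 20),
    n_seeds: int = 12,
    seed: int = 0,
    config=None,
    **scene_kwargs,
):
    """Thickness error vs number of grains; one row per (n_grains, replicate)."""
    import pandas as pd

    root = np.random.default_rng(seed)
    rows = []
    for n in sample_sizes:
        for rep in range(n_seeds):
            s = int(root.integers(2**31))
            ev = evaluate_scene(_scene_for(n, s, None, **scene_kwargs), config)
            rows.append(
                {
                    "n_grains": n,
                    "replicate": rep,
                    "seed": s,
                    "thickness_mm": ev.thickness_mm,
                    "error_mm": ev.error_mm,
                    "reconstruction_error_mm": ev.reconstruction_error_mm,
                    "n_measured": ev.n_grains_measured,
                }
            )
    return pd.DataFrame(rows)


def sweep_baseline(
    baselines=(40.0, 60.0, 80.0, 100.0),
    n_seeds: int = 5,
    n_grains: int = 10,
    seed: int = 0,
    config=None,
    **scene_kwargs,
):
    """Thickness error vs stereo baseline; one row per (baseline, replicate)."""
    import pandas as pd

    root = np.random.default_rng(seed)
    rows = []
    for b in baselines:
        for rep in range(n_seeds):
            s = int(root.integers(2**31))
            ev = evaluate_scene(_scene_for(n_grains, s, float(b), **scene_kwargs), config)
            rows.append(
                {
                    "baseline_mm": float(b),
                    "base_height_ratio": float(b) / RigParams().camera_height,
                    "replicate": rep,
                    "seed": s,
                    "thickness_mm": ev.thickness_mm,
                    "error_mm": ev.error_mm,
                    "reconstruction_error_mm": ev.reconstruction_error_mm,
                    "n_measured": ev.n_grains_measured,
                }
            )
    return pd.DataFrame(rows)
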