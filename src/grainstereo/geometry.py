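"""Pinhole photogrammetric camera model.

Implements the collinearity relation between object space and photo
coordinates, Euler-angle (phi, omega, kappa) rotation matrices, Brown-Conrady
lens distortion with iterative inversion, single-image space resection
(Gauss-Newton) and two-ray space intersection (linear least squares plus one
Gauss-Newton refinement step).

Conventions
-----------
* Object space: right-handed, millimetres, Z up; the calibration board lies
  in the Z = 0 plane and cameras sit at Zs > 0.
* Photo coordinates: principal-point-referenced, pixels, x right and y up.
  ``project`` returns exactly the collinearity left-hand sides (x - x0,
  y - y0); the principal point enters only when converting to raster indices.
* Raster indices: 0-based (row, col) with the origin at the top-left pixel
  centre and rows increasing downward.  For an image of width W and height H::

      x = (col - W / 2) - x0          col = x + x0 + W / 2
      y = (H / 2 - row) - y0          row = H / 2 - (y + y0)

* Rotation: the photo vector (x - x0, y - y0, -f) equals
  ``lambda * R_phi @ R_omega @ R_kappa @ (X - Xs, Y - Ys, Z - Zs)`` with the
  Y-, X- and Z-axis factor matrices applied in that order.
* Angles are radians internally; YAML configs may declare degrees with an
  explicit ``angle_unit`` key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    ConvergenceError,
    DegenerateGeometryError,
    InsufficientControlError,
    SingularGeometryError,
)

__all__ = [
    "InteriorOrientation",
    "DistortionCoefficients",
    "ExteriorOrientation",
    "CameraModel",
    "ResectionResult",
    "rotation_matrix",
    "project",
    "distort_points",
    "undistort_points",
    "space_resection",
    "space_intersection",
    "intersect_many",
    "photo_from_raster",
    "raster_from_photo",
    "load_camera",
    "save_camera",
]


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InteriorOrientation:
    """Principal point offset (x0, y0) and principal distance f, in pixels."""

    x0: float = 0.0
    y0: float = 0.0
    f: float = 1.0

    def __post_init__(self) -> None:
        if not (self.f > 0):
            raise ConfigError(f"principal distance must be positive, got {self.f}")


@dataclass(frozen=True)
class DistortionCoefficients:
    """Brown-Conrady radial (k1, k2, k3) and tangential (p1, p2) coefficients.

    Coefficients apply to photo coordinates normalised by the principal
    distance, so their magnitudes are comparable to those reported by
    standard single-plane checkerboard calibrators.  All-zero means a
    distortion-free lens.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.k3, self.p1, self.p2)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigError("distortion coefficients must be finite")

    @property
    def is_zero(self) -> bool:
        return not any((self.k1, self.k2, self.k3, self.p1, self.p2))


@dataclass(frozen=True)
class ExteriorOrientation:
    """Projection centre (Xs, Ys, Zs) in mm and attitude angles in radians."""

    Xs: float = 0.0
    Ys: float = 0.0
    Zs: float = 1.0
    phi: float = 0.0
    omega: float = 0.0
    kappa: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Xs, self.Ys, self.Zs, self.phi, self.omega, self.kappa])

    @classmethod
    def from_array(cls, p: np.ndarray) -> "ExteriorOrientation":
        return cls(*[float(v) for v in p])

    @property
    def position(self) -> np.ndarray:
        return np.array([self.Xs, self.Ys, self.Zs])

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.phi, self.omega, self.kappa)


def rotation_matrix(phi: float, omega: float, kappa: float) -> np.ndarray:
    """Return R = R_phi @ R_omega @ R_kappa (Y-, X-, Z-axis factors).

    The product of three orthonormal factors; orthonormal with det +1.
    """
    cp, sp = math.cos(phi), math.sin(phi)
    co, so = math.cos(omega), math.sin(omega)
    ck, sk = math.cos(kappa), math.sin(kappa)
    r_phi = np.array([[cp, 0.0, -sp], [0.0, 1.0, 0.0], [sp, 0.0, cp]])
    r_omega = np.array([[1.0, 0.0, 0.0], [0.0, co, -so], [0.0, so, co]])
    r_kappa = np.array([[ck, -sk, 0.0], [sk, ck, 0.0], [0.0, 0.0, 1.0]])
    return r_phi @ r_omega @ r_kappa


# --------------------------------------------------------------------------
# Projection and distortion
# --------------------------------------------------------------------------

def _as_points(points, dim: int) -> tuple[np.ndarray, bool]:
    """Coerce to a (N, dim) float array; report whether input was a single point."""
    a = np.asarray(points, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    if a.shape[-1] != dim:
        raise ConfigError(f"expected points with {dim} coordinates, got shape {a.shape}")
    return a, single


def project(points, eo: ExteriorOrientation, io: InteriorOrientation) -> np.ndarray:
    """Project object points (mm) to principal-point-referenced photo coords (px).

    Raises :class:`DegenerateGeometryError` if any point lies in the camera's
    focal plane (denominator below 1e-12).
    """
    pts, single = _as_points(points, 3)
    r = eo.rotation
    d = pts - eo.position
    u = d @ r.T
    den = u[:, 2]
    if np.any(np.abs(den) < 1e-12):
        raise DegenerateGeometryError("object point lies in the camera focal plane")
    xy = -io.f * u[:, :2] / den[:, None]
    return xy[0] if single else xy


def _apply_brown_conrady(xn: np.ndarray, yn: np.ndarray, dist: DistortionCoefficients):
    r2 = xn * xn + yn * yn
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    dx = 2.0 * dist.p1 * xn * yn + dist.p2 * (r2 + 2.0 * xn * xn)
    dy = dist.p1 * (r2 + 2.0 * yn * yn) + 2.0 * dist.p2 * xn * yn
    return xn * radial + dx, yn * radial + dy


def distort_points(points, io: InteriorOrientation, dist: DistortionCoefficients) -> np.ndarray:
    """Apply the forward Brown-Conrady model to ideal photo coordinates."""
    pts, single = _as_points(points, 2)
    if dist.is_zero:
        out = pts.copy()
        return out[0] if single else out
    xn, yn = pts[:, 0] / io.f, pts[:, 1] / io.f
    xd, yd = _apply_brown_conrady(xn, yn, dist)
    out = np.column_stack([xd, yd]) * io.f
    return out[0] if single else out


def undistort_points(
    points,
    io: InteriorOrientation,
    dist: DistortionCoefficients,
    *,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the Brown-Conrady model by fixed-point iteration.

    Converges to a forward-reprojection residual below ``tol`` pixels;
    raises :class:`ConvergenceError` after ``max_iter`` sweeps (a sign of
    implausibly large coefficients).
    """
    pts, single = _as_points(points, 2)
    if dist.is_zero:
        out = pts.copy()
        return out[0] if single else out
    xd, yd = pts[:, 0] / io.f, pts[:, 1] / io.f
    xn, yn = xd.copy(), yd.copy()
    tol_n = tol / io.f
    for _ in range(max_iter):
        r2 = xn * xn + yn * yn
        radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
        tx = 2.0 * dist.p1 * xn * yn + dist.p2 * (r2 + 2.0 * xn * xn)
        ty = dist.p1 * (r2 + 2.0 * yn * yn) + 2.0 * dist.p2 * xn * yn
        xn = (xd - tx) / radial
        yn = (yd - ty) / radial
        fx, fy = _apply_brown_conrady(xn, yn, dist)
        if max(np.abs(fx - xd).max(initial=0.0), np.abs(fy - yd).max(initial=0.0)) < tol_n:
            out = np.column_stack([xn, yn]) * io.f
            return out[0] if single else out
    raise ConvergenceError("undistortion did not converge; check distortion coefficients")


# --------------------------------------------------------------------------
# Raster <-> photo conversion
# --------------------------------------------------------------------------

def photo_from_raster(rowcol, image_size: tuple[int, int], io: InteriorOrientation) -> np.ndarray:
    """(row, col) raster indices -> principal-point-referenced photo (x, y)."""
    rc, single = _as_points(rowcol, 2)
    w, h = image_size
    x = rc[:, 1] - w / 2.0 - io.x0
    y = (h / 2.0 - rc[:, 0]) - io.y0
    out = np.column_stack([x, y])
    return out[0] if single else out


def raster_from_photo(xy, image_size: tuple[int, int], io: InteriorOrientation) -> np.ndarray:
    """Photo (x, y) -> raster (row, col); inverse of :func:`photo_from_raster`."""
    pts, single = _as_points(xy, 2)
    w, h = image_size
    col = pts[:, 0] + io.x0 + w / 2.0
    row = h / 2.0 - (pts[:, 1] + io.y0)
    out = np.column_stack([row, col])
    return out[0] if single else out


# --------------------------------------------------------------------------
# Camera model
# --------------------------------------------------------------------------

@dataclass
class CameraModel:
    """Interior + exterior orientation, distortion and (optionally) image size.

    ``eo`` may be None for a not-yet-oriented camera; orientation-dependent
    methods then raise :class:`ConfigError`.
    ``image_size`` is (width, height) in pixels and is required only for
    raster conversions.
    """

    io: InteriorOrientation
    eo: ExteriorOrientation | None = None
    distortion: DistortionCoefficients = field(default_factory=DistortionCoefficients)
    image_size: tuple[int, int] | None = None

    # -- orientation-dependent geometry ------------------------------------
    def _require_eo(self) -> ExteriorOrientation:
        if self.eo is None:
            raise ConfigError("camera is not oriented (exterior orientation missing)")
        return self.eo

    def project(self, points) -> np.ndarray:
        """Ideal (distortion-free) photo coordinates of object points."""
        return project(points, self._require_eo(), self.io)

    def project_distorted(self, points) -> np.ndarray:
        """Photo coordinates including forward lens distortion (for rendering)."""
        return distort_points(self.project(points), self.io, self.distortion)

    def back_project_to_plane(self, xy, z: float = 0.0) -> np.ndarray:
        """Intersect the ray(s) of ideal photo point(s) with the plane Z = z."""
        eo = self._require_eo()
        pts, single = _as_points(xy, 2)
        r = eo.rotation
        d = np.column_stack([pts, np.full(len(pts), -self.io.f)]) @ r  # R^T rows
        if np.any(np.abs(d[:, 2]) < 1e-15):
            raise DegenerateGeometryError("ray parallel to the Z plane")
        t = (z - eo.Zs) / d[:, 2]
        out = eo.position + t[:, None] * d
        return out[0] if single else out

    # -- distortion --------------------------------------------------------
    def undistort_points(self, xy) -> np.ndarray:
        return undistort_points(xy, self.io, self.distortion)

    def distort_points(self, xy) -> np.ndarray:
        return distort_points(xy, self.io, self.distortion)

    # -- raster conversions ------------------------------------------------
    def _require_size(self) -> tuple[int, int]:
        if self.image_size is None:
            raise ConfigError("camera has no image_size; raster conversion impossible")
        return self.image_size

    def photo_from_raster(self, rowcol) -> np.ndarray:
        return photo_from_raster(rowcol, self._require_size(), self.io)

    def raster_from_photo(self, xy) -> np.ndarray:
        return raster_from_photo(xy, self._require_size(), self.io)

    def with_eo(self, eo: ExteriorOrientation) -> "CameraModel":
        return replace(self, eo=eo)


# --------------------------------------------------------------------------
# Space resection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResectionResult:
    """Solved exterior orientation with its RMS image residual (pixels)."""

    eo: ExteriorOrientation
    rms: float
    n_iterations: int
    n_points: int


def _control_arrays(control) -> tuple[np.ndarray, np.ndarray]:
    """Accept ControlPoint-like objects (``.object``/``.image``) or two arrays."""
    if isinstance(control, tuple) and len(control) == 2:
        obj = np.asarray(control[0], dtype=float)
        img = np.asarray(control[1], dtype=float)
    else:
        obj = np.array([np.asarray(c.object, dtype=float) for c in control])
        img = np.array([np.asarray(c.image, dtype=float) for c in control])
    obj = obj.reshape(-1, 3)
    img = img.reshape(-1, 2)
    if len(obj) != len(img):
        raise ConfigError("object and image point counts differ")
    return obj, img


def default_resection_initial(
    obj: np.ndarray, img: np.ndarray, io: InteriorOrientation
) -> ExteriorOrientation:
    """Nadir-attitude initial guess: (Xs, Ys) at the control centroid, Zs from scale.

    Zs is the principal distance times the ratio of the control-point extent
    in object space (mm) to its extent in the image (px) — adequate for
    near-nadir rigs.
    """
    cx, cy = obj[:, 0].mean(), obj[:, 1].mean()
    obj_diag = float(np.linalg.norm(np.ptp(obj[:, :2], axis=0)))
    img_diag = float(np.linalg.norm(np.ptp(img, axis=0)))
    if obj_diag <= 0 or img_diag <= 0:
        raise SingularGeometryError("control points coincide; cannot scale initial guess")
    zs = io.f * obj_diag / img_diag
    return ExteriorOrientation(cx, cy, zs, 0.0, 0.0, 0.0)


_RESECTION_STEPS = np.array([1e-4, 1e-4, 1e-4, 1e-7, 1e-7, 1e-7])


def space_resection(
    control,
    io: InteriorOrientation,
    initial: ExteriorOrientation | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ResectionResult:
    """Solve one camera's exterior orientation from >= 4 control points.

    Gauss-Newton on the linearised collinearity equations; converges when the
    largest parameter update falls below ``tol``.  Distinguishes singular
    normal equations (:class:`SingularGeometryError`) from non-convergence
    (:class:`ConvergenceError`).
    """
    obj, img = _control_arrays(control)
    n = len(obj)
    if n < 4:
        raise InsufficientControlError(
            f"space resection needs at least 4 control points, got {n}"
        )
    centered = obj - obj.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise SingularGeometryError("control points are collinear in object space")

    if initial is None:
        initial = default_resection_initial(obj, img, io)
    p = initial.as_array()

    def residuals(params: np.ndarray) -> np.ndarray:
        eo = ExteriorOrientation.from_array(params)
        return (img - project(obj, eo, io)).ravel()

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = residuals(p)
        jac = np.empty((2 * n, 6))
        for k in range(6):
            h = _RESECTION_STEPS[k]
            pp, pm = p.copy(), p.copy()
            pp[k] += h
            pm[k] -= h
            jac[:, k] = (residuals(pp) - residuals(pm)) / (2.0 * h)  # dr/dp
        u, s, vt = np.linalg.svd(jac, full_matrices=False)
        if s[-1] < 1e-12 * s[0]:
            raise SingularGeometryError("singular normal equations in resection")
        dp = vt.T @ ((u.T @ r) / s)
        p = p - dp
        if np.max(np.abs(dp)) < tol:
            break
    else:
        raise ConvergenceError(f"space resection did not converge in {max_iter} iterations")

    r = residuals(p)
    rms = float(np.sqrt(np.mean(r**2)))
    return ResectionResult(ExteriorOrientation.from_array(p), rms, n_iter, n)


# --------------------------------------------------------------------------
# Space intersection
# --------------------------------------------------------------------------

def _intersection_rows(xy: np.ndarray, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Rearranged collinearity equations, linear in the object point P.

    Each observation (x, y) gives two equations
    ``(x * r3 + f * r1) . P = (x * r3 + f * r1) . S`` (and y with r2).
    Returns A with shape (N, 2, 3) and b with shape (N, 2).
    """
    eo = cam._require_eo()
    r = eo.rotation
    f = cam.io.f
    a1 = xy[:, 0:1] * r[2] + f * r[0]
    a2 = xy[:, 1:2] * r[2] + f * r[1]
    a = np.stack([a1, a2], axis=1)
    b = a @ eo.position
    return a, b


def _reprojection_residuals(
    p: np.ndarray, left_xy: np.ndarray, right_xy: np.ndarray,
    left_cam: CameraModel, right_cam: CameraModel,
) -> np.ndarray:
    rl = left_xy - project(p, left_cam.eo, left_cam.io)
    rr = right_xy - project(p, right_cam.eo, right_cam.io)
    return np.concatenate([rl, rr], axis=1)  # (N, 4)


def intersect_many(
    left_xy,
    right_xy,
    left_cam: CameraModel,
    right_cam: CameraModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised space intersection of N corresponding photo-point pairs.

    Linear least squares on the rearranged collinearity equations followed by
    one Gauss-Newton refinement step (kept only where it lowers the
    reprojection residual).  Returns (points (N, 3) in mm, RMS residual (N,)
    in pixels).
    """
    lxy, _ = _as_points(left_xy, 2)
    rxy, _ = _as_points(right_xy, 2)
    if len(lxy) != len(rxy):
        raise ConfigError("left and right observation counts differ")
    al, bl = _intersection_rows(lxy, left_cam)
    ar, br = _intersection_rows(rxy, right_cam)
    a = np.concatenate([al, ar], axis=1)          # (N, 4, 3)
    b = np.concatenate([bl, br], axis=1)          # (N, 4)
    at = a.transpose(0, 2, 1)
    m = at @ a
    v = (at @ b[:, :, None])[:, :, 0]
    try:
        p = np.linalg.solve(m, v[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological batch
        raise DegenerateGeometryError("singular intersection geometry") from exc

    def resid(pts: np.ndarray) -> np.ndarray:
        return _reprojection_residuals(pts, lxy, rxy, left_cam, right_cam)

    r0 = resid(p)
    eps = 1e-6
    jac = np.empty((len(p), 4, 3))
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = eps
        jac[:, :, k] = (resid(p + dp) - resid(p - dp)) / (2.0 * eps)  # dr/dP
    jt = jac.transpose(0, 2, 1)
    jtj = jt @ jac
    jtr = (jt @ r0[:, :, None])[:, :, 0]
    try:
        step = np.linalg.solve(jtj, jtr[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateGeometryError("singular intersection geometry") from exc
    p_ref = p - step
    r1 = resid(p_ref)
    rms0 = np.sqrt(np.mean(r0**2, axis=1))
    rms1 = np.sqrt(np.mean(r1**2, axis=1))
    better = rms1 < rms0
    p[better] = p_ref[better]
    rms = np.where(better, rms1, rms0)
    return p, rms


def space_intersection(
    left_obs,
    right_obs,
    left_cam: CameraModel,
    right_cam: CameraModel,
) -> tuple[np.ndarray, float]:
    """Intersect one pair of corresponding photo points into an object point.

    Returns (object point (3,) in mm, RMS reprojection residual in pixels).
    Near-parallel rays (e.g. zero baseline) raise
    :class:`DegenerateGeometryError`.
    """
    lxy = np.asarray(left_obs, dtype=float).reshape(1, 2)
    rxy = np.asarray(right_obs, dtype=float).reshape(1, 2)
    al, bl = _intersection_rows(lxy, left_cam)
    ar, br = _intersection_rows(rxy, right_cam)
    a = np.concatenate([al, ar], axis=1)[0]
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise DegenerateGeometryError("rays nearly parallel; intersection is degenerate")
    pts, rms = intersect_many(lxy, rxy, left_cam, right_cam)
    return pts[0], float(rms[0])


# --------------------------------------------------------------------------
# Config I/O
# --------------------------------------------------------------------------

def _eo_from_mapping(m: dict) -> ExteriorOrientation:
    unit = str(m.get("angle_unit", "radians")).lower()
    scale = math.pi / 180.0 if unit.startswith("deg") else 1.0
    if not unit.startswith(("deg", "rad")):
        raise ConfigError(f"unknown angle_unit {unit!r}")
    return ExteriorOrientation(
        Xs=float(m["Xs"]), Ys=float(m["Ys"]), Zs=float(m["Zs"]),
        phi=float(m.get("phi", 0.0)) * scale,
        omega=float(m.get("omega", 0.0)) * scale,
        kappa=float(m.get("kappa", 0.0)) * scale,
    )


def camera_from_dict(d: dict) -> CameraModel:
    try:
        io_m = d["io"]
        io = InteriorOrientation(
            x0=float(io_m.get("x0", 0.0)), y0=float(io_m.get("y0", 0.0)), f=float(io_m["f"])
        )
    except KeyError as exc:
        raise ConfigError(f"camera config missing key: {exc}") from exc
    dist_m = d.get("distortion", {}) or {}
    dist = DistortionCoefficients(**{k: float(v) for k, v in dist_m.items()})
    eo = _eo_from_mapping(d["eo"]) if d.get("eo") else None
    size = d.get("image_size")
    image_size = (int(size[0]), int(size[1])) if size else None
    return CameraModel(io=io, eo=eo, distortion=dist, image_size=image_size)


def camera_to_dict(cam: CameraModel) -> dict:
    d: dict = {
        "io": {"x0": cam.io.x0, "y0": cam.io.y0, "f": cam.io.f},
        "distortion": {
            "k1": cam.distortion.k1, "k2": cam.distortion.k2, "k3": cam.distortion.k3,
            "p1": cam.distortion.p1, "p2": cam.distortion.p2,
        },
    }
    if cam.eo is not None:
        d["eo"] = {
            "Xs": cam.eo.Xs, "Ys": cam.eo.Ys, "Zs": cam.eo.Zs,
            "phi": cam.eo.phi, "omega": cam.eo.omega, "kappa": cam.eo.kappa,
            "angle_unit": "radians",
        }
    if cam.image_size is not None:
        d["image_size"] = [int(cam.image_size[0]), int(cam.image_size[1])]
    return d


def load_camera(path) -> CameraModel:
    """Load a camera from a YAML (or JSON, a YAML subset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"camera config {path} is not a mapping")
    return camera_from_dict(data)


def save_camera(cam: CameraModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(camera_to_dict(cam), fh, sort_keys=False)
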