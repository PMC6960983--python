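"""Camera-model oracles: rotation, projection, distortion, resection, intersection."""

import numpy as np
import pytest

from grainstereo import geometry as g
from grainstereo.errors import (
    ConfigError,
    DegenerateGeometryError,
    InsufficientControlError,
    SingularGeometryError,
)

IO = g.InteriorOrientation(0.0, 0.0, 3500.0)


def random_rig(rng):
    """A well-conditioned near-nadir stereo rig with mild random attitude."""
    base = rng.uniform(40.0, 120.0)
    height = rng.uniform(250.0, 450.0)
    def cam(x):
        eo = g.ExteriorOrientation(
            x, rng.uniform(-20, 20), height,
            rng.uniform(-0.05, 0.05), rng.uniform(-0.05, 0.05), rng.uniform(-0.3, 0.3),
        )
        return g.CameraModel(IO, eo)
    return cam(rng.uniform(-30, 0)), cam(base)


class TestRotationMatrix:
    def test_zero_angles_is_identity(self):
        assert np.allclose(g.rotation_matrix(0, 0, 0), np.eye(3))

    def test_phi_quarter_turn(self):
        # product of the three factor matrices evaluated independently
        expected = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        assert np.allclose(g.rotation_matrix(np.pi / 2, 0, 0), expected, atol=1e-15)

    def test_matches_factor_product(self):
        phi, omega, kappa = 0.3, -0.2, 1.1
        cp, sp = np.cos(phi), np.sin(phi)
        co, so = np.cos(omega), np.sin(omega)
        ck, sk = np.cos(kappa), np.sin(kappa)
        r_phi = np.array([[cp, 0, -sp], [0, 1, 0], [sp, 0, cp]])
        r_om = np.array([[1, 0, 0], [0, co, -so], [0, so, co]])
        r_ka = np.array([[ck, -sk, 0], [sk, ck, 0], [0, 0, 1]])
        assert np.allclose(
            g.rotation_matrix(phi, omega, kappa), r_phi @ r_om @ r_ka, atol=1e-14
        )

    def test_orthonormal_det_plus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            r = g.rotation_matrix(*rng.uniform(-np.pi, np.pi, 3))
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-10)
            assert abs(np.linalg.det(r) - 1.0) < 1e-10


class TestProject:
    def test_optical_axis_maps_to_principal_point(self):
        io = g.InteriorOrientation(0, 0, 5000)
        eo = g.ExteriorOrientation(0, 0, 350)
        assert np.allclose(g.project([0.0, 0.0, 0.0], eo, io), [0.0, 0.0])

    def test_hand_evaluated_nadir_point(self):
        io = g.InteriorOrientation(0, 0, 5000)
        eo = g.ExteriorOrientation(0, 0, 350)
        xy = g.project([7.0, 0.0, 0.0], eo, io)
        assert np.allclose(xy, [100.0, 0.0])  # -f * 7 / (0 - 350)

    def test_focal_plane_is_degenerate(self):
        eo = g.ExteriorOrientation(0, 0, 350)
        with pytest.raises(DegenerateGeometryError):
            g.project([5.0, 5.0, 350.0], eo, IO)

    def test_project_intersect_closure(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(1000):
            caml, camr = random_rig(rng)
            p = np.array([rng.uniform(-30, 60), rng.uniform(-30, 60), rng.uniform(0, 5)])
            q, rms = g.space_intersection(caml.project(p), camr.project(p), caml, camr)
            worst = max(worst, float(np.abs(q - p).max()))
            assert rms < 1e-6
        assert worst < 1e-6


class TestDistortion:
    DIST = g.DistortionCoefficients(k1=-0.12, k2=0.035, k3=-0.002, p1=8e-4, p2=-5e-4)

    def test_zero_coefficients_identity(self):
        pts = np.array([[12.3, -45.6], [0.0, 0.0], [700.0, 300.0]])
        out = g.undistort_points(pts, IO, g.DistortionCoefficients())
        assert np.array_equal(out, pts)

    def test_distort_undistort_roundtrip(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-900, 900, (200, 2))
        recovered = g.undistort_points(g.distort_points(pts, IO, self.DIST), IO, self.DIST)
        assert np.abs(recovered - pts).max() < 1e-6

    def test_principal_point_unmoved(self):
        out = g.distort_points([0.0, 0.0], IO, self.DIST)
        assert np.allclose(out, [0.0, 0.0])
        out = g.undistort_points([0.0, 0.0], IO, self.DIST)
        assert np.allclose(out, [0.0, 0.0])


class TestRasterPhotoConversion:
    def test_bijection(self):
        io = g.InteriorOrientation(1.5, -2.0, 3500)
        rng = np.random.default_rng(3)
        rc = rng.uniform(0, 600, (50, 2))
        xy = g.photo_from_raster(rc, (800, 600), io)
        back = g.raster_from_photo(xy, (800, 600), io)
        assert np.abs(back - rc).max() < 1e-12

    def test_documented_convention(self):
        io = g.InteriorOrientation(0.0, 0.0, 3500)
        # image centre maps to the principal point
        assert np.allclose(g.photo_from_raster([300.0, 400.0], (800, 600), io), [0, 0])
        # one pixel right -> +x; one pixel down -> -y
        assert np.allclose(g.photo_from_raster([300.0, 401.0], (800, 600), io), [1, 0])
        assert np.allclose(g.photo_from_raster([301.0, 400.0], (800, 600), io), [0, -1])


def synthetic_control(eo, io, n=25, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    obj = np.column_stack([rng.uniform(0, 80, n), rng.uniform(0, 48, n), np.zeros(n)])
    img = g.project(obj, eo, io)
    if noise:
        img = img + rng.normal(0, noise, img.shape)
    return obj, img


class TestSpaceResection:
    TRUE = g.ExteriorOrientation(12.0, 30.0, 355.0, 0.02, -0.03, 0.15)

    def test_exact_recovery_noise_free(self):
        obj, img = synthetic_control(self.TRUE, IO)
        res = g.space_resection((obj, img), IO)
        err = np.abs(res.eo.as_array() - self.TRUE.as_array())
        assert err[:3].max() < 1e-6      # mm
        assert err[3:].max() < 1e-8      # rad
        assert res.rms < 1e-8

    def test_noisy_rms_matches_least_squares_theory(self):
        # E[rms^2] = sigma^2 * (2n - 6) / (2n); check the order of magnitude by MC
        sigma, n = 0.2, 25
        rms_vals = []
        for rep in range(20):
            obj, img = synthetic_control(self.TRUE, IO, n=n, seed=100 + rep, noise=sigma)
            rms_vals.append(g.space_resection((obj, img), IO).rms)
        expected = sigma * np.sqrt(1 - 6 / (2 * n))
        assert 0.7 * expected < np.mean(rms_vals) < 1.3 * expected

    def test_three_points_insufficient(self):
        obj, img = synthetic_control(self.TRUE, IO, n=3)
        with pytest.raises(InsufficientControlError):
            g.space_resection((obj, img), IO)

    def test_collinear_control_singular(self):
        t = np.linspace(0, 60, 8)
        obj = np.column_stack([t, 0.5 * t, np.zeros(8)])
        img = g.project(obj, self.TRUE, IO)
        with pytest.raises(SingularGeometryError):
            g.space_resection((obj, img), IO)


class TestSpaceIntersection:
    def cams(self):
        caml = g.CameraModel(IO, g.ExteriorOrientation(0, 24, 350))
        camr = g.CameraModel(IO, g.ExteriorOrientation(80, 24, 350))
        return caml, camr

    def test_recovers_known_point(self):
        caml, camr = self.cams()
        p = np.array([12.0, 30.0, 0.85])
        q, rms = g.space_intersection(caml.project(p), camr.project(p), caml, camr)
        assert np.abs(q - p).max() < 1e-8
        assert rms < 1e-10

    def test_board_points_reconstruct_to_datum(self):
        caml, camr = self.cams()
        pts = np.array([[0.0, 0.0, 0.0], [80.0, 48.0, 0.0], [40.0, 24.0, 0.0]])
        rec, _ = g.intersect_many(caml.project(pts), camr.project(pts), caml, camr)
        assert np.abs(rec[:, 2]).max() < 1e-8

    def test_zero_baseline_degenerate(self):
        caml, _ = self.cams()
        p = np.array([12.0, 30.0, 0.85])
        xy = caml.project(p)
        with pytest.raises(DegenerateGeometryError):
            g.space_intersection(xy, xy, caml, caml)

    def test_unoriented_camera_rejected(self):
        caml, camr = self.cams()
        blank = g.CameraModel(IO)
        with pytest.raises(ConfigError):
            g.space_intersection([0, 0], [0, 0], blank, camr)


class TestCameraConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cam = g.CameraModel(
            io=g.InteriorOrientation(1.2, -0.5, 3500),
            eo=g.ExteriorOrientation(0, 24, 350, 0.01, -0.02, 0.3),
            distortion=g.DistortionCoefficients(k1=-0.1, p1=1e-4),
            image_size=(1760, 640),
        )
        path = tmp_path / "cam.yaml"
        g.save_camera(cam, path)
        loaded = g.load_camera(path)
        assert loaded.io == cam.io
        assert loaded.distortion == cam.distortion
        assert np.allclose(loaded.eo.as_array(), cam.eo.as_array())
        assert loaded.image_size == cam.image_size

    def test_degrees_angle_unit(self, tmp_path):
        path = tmp_path / "cam.yaml"
        path.write_text(
            "io: {x0: 0, y0: 0, f: 3500}\n"
            "eo: {Xs: 0, Ys: 0, Zs: 350, phi: 0, omega: 0, kappa: 90, angle_unit: degrees}\n"
        )
        cam = g.load_camera(path)
        assert abs(cam.eo.kappa - np.pi / 2) < 1e-12
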