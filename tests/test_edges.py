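"""Polar signatures, circular-correlation alignment, grain correspondence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainstereo import edges, geometry as g, segmentation as seg
from grainstereo.board import detect_circle_centers
from grainstereo.errors import ProfileError
from conftest import asymmetric_profile


def rasterized_shape(kind="ellipse", a=50, b=10):
    yy, xx = np.mgrid[0:140, 0:140]
    if kind == "circle":
        m = (yy - 70) ** 2 + (xx - 70) ** 2 <= a**2
    else:
        m = ((yy - 70) / b) ** 2 + ((xx - 70) / a) ** 2 <= 1
    boundary = seg.trace_boundary(m)
    centroid = seg.region_centroid(m)
    bxy = np.column_stack([boundary[:, 1], -boundary[:, 0]]).astype(float)
    cxy = np.array([centroid[1], -centroid[0]])
    return bxy, cxy


class TestPolarDistances:
    def test_circle_is_flat(self):
        bxy, cxy = rasterized_shape("circle", a=20)
        _, d = edges.polar_distances(bxy, cxy)
        assert np.abs(d - 20).max() < 1.0  # digital-circle inner corners

    def test_ellipse_axes(self):
        bxy, cxy = rasterized_shape("ellipse", a=50, b=10)
        ang, d = edges.polar_distances(bxy, cxy)
        h = edges.resample_profile(ang, d)
        assert h[0] == pytest.approx(50, abs=1.0)
        assert h[90] == pytest.approx(10, abs=1.0)
        assert h[180] == pytest.approx(50, abs=1.0)

    def test_angles_increase_after_unwrap(self):
        bxy, cxy = rasterized_shape("ellipse")
        ang, _ = edges.polar_distances(bxy, cxy)
        unwrapped = np.unwrap(np.radians(ang))
        # CCW ordering: strictly increasing up to rasterisation jitter
        assert np.sum(np.diff(unwrapped) <= 0) <= len(ang) * 0.02
        assert unwrapped[-1] - unwrapped[0] > 0.95 * 2 * np.pi

    def test_centroid_outside_rejected(self):
        bxy, cxy = rasterized_shape("ellipse")
        with pytest.raises(ProfileError):
            edges.polar_distances(bxy, cxy + [200.0, 0.0])


class TestResampleProfile:
    def test_identity_at_integer_degrees(self):
        ang = np.arange(360.0)
        d = 30 + np.sin(np.radians(ang) * 2)
        h = edges.resample_profile(ang, d)
        assert np.allclose(h, d)

    def test_linear_midpoint(self):
        ang = np.concatenate([[0.0, 2.0], np.arange(10.0, 360.0, 10.0)])
        d = np.concatenate([[10.0, 14.0], np.full(35, 12.0)])
        h = edges.resample_profile(ang, d)
        assert h[1] == pytest.approx(12.0)

    def test_circle_any_density(self):
        bxy, cxy = rasterized_shape("circle", a=20)
        ang, d = edges.polar_distances(bxy, cxy)
        h = edges.resample_profile(ang, d)
        assert np.abs(h - 20).max() < 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_interpolation_cannot_overshoot(self, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 360, 80))
        d = rng.uniform(5, 40, 80)
        h = edges.resample_profile(ang, d, max_gap_deg=360.0)
        assert d.min() - 1e-9 <= h.min() and h.max() <= d.max() + 1e-9

    def test_large_gap_rejected(self):
        with pytest.raises(ProfileError):
            edges.resample_profile([0.0, 2.0, 120.0, 240.0], [10.0, 14.0, 12.0, 12.0])


def _profile(h):
    return edges.EdgeProfile(h=h, centroid=np.zeros(2))


class TestMatchEdgePoints:
    def test_self_match(self):
        p = _profile(asymmetric_profile())
        m = edges.match_edge_points(p, p)
        assert m.shift == 0
        assert m.correlation == pytest.approx(1.0)

    def test_constructed_shift_recovered(self):
        h = asymmetric_profile()
        right = np.empty(360)
        right[(np.arange(360) + 37) % 360] = h  # left angle i appears at right i+37
        m = edges.match_edge_points(_profile(h), _profile(right))
        assert m.shift == 37
        assert m.correlation == pytest.approx(1.0)

    def test_all_360_shifts_exact(self):
        h = asymmetric_profile()
        for k in range(360):
            right = np.empty(360)
            right[(np.arange(360) + k) % 360] = h
            m = edges.match_edge_points(_profile(h), _profile(right))
            assert m.shift == k

    def test_noisy_shift_recovery(self):
        rng = np.random.default_rng(7)
        h = asymmetric_profile()
        hits = 0
        for _ in range(100):
            k = int(rng.integers(0, 360))
            right = np.empty(360)
            right[(np.arange(360) + k) % 360] = h
            right += rng.normal(0, 0.2, 360)
            m = edges.match_edge_points(_profile(h), _profile(right))
            hits += m.shift == k
        assert hits >= 99

    def test_left_right_symmetry(self):
        rng = np.random.default_rng(8)
        h = asymmetric_profile(rng)
        k = 123
        right = np.empty(360)
        right[(np.arange(360) + k) % 360] = asymmetric_profile()
        f = edges.match_edge_points(_profile(h), _profile(right))
        b = edges.match_edge_points(_profile(right), _profile(h))
        assert f.correlation == pytest.approx(b.correlation, abs=1e-12)
        assert (f.shift + b.shift) % 360 == 0

    def test_zero_variance_flagged(self):
        m = edges.match_edge_points(_profile(np.full(360, 25.0)), _profile(asymmetric_profile()))
        assert m.degenerate and m.shift == 0

    def test_symmetric_profile_yields_both_candidates(self):
        th = np.radians(np.arange(360))
        h = 40 + 25 * np.cos(2 * th)  # exactly 2-fold symmetric
        right = np.empty(360)
        right[(np.arange(360) + 50) % 360] = h
        cands = edges.candidate_shifts(_profile(h), _profile(right))
        shifts = {c.shift for c in cands}
        assert 50 in shifts and 230 in shifts


class TestCorrespondenceToPoints:
    def test_polar_to_cartesian(self):
        h = asymmetric_profile()
        h[0] = 20.0
        left = edges.EdgeProfile(h=h, centroid=np.array([100.0, 100.0]))
        m = edges.EdgeCorrespondence(shift=0, correlation=1.0)
        lp, rp = edges.correspondence_to_image_points(m, left, left)
        assert lp.shape == (360, 2) and rp.shape == (360, 2)
        assert np.allclose(lp[0], [120.0, 100.0])

    def test_points_lie_on_traced_boundary(self):
        bxy, cxy = rasterized_shape("ellipse")
        prof = edges.profile_from_boundary(bxy, cxy)
        m = edges.EdgeCorrespondence(shift=0, correlation=1.0)
        lp, _ = edges.correspondence_to_image_points(m, prof, prof)
        d = np.linalg.norm(lp[:, None, :] - bxy[None, :, :], axis=2).min(axis=1)
        assert d.max() < 1.0


class TestMatchGrains:
    def test_hundred_random_configurations_fully_correct(self):
        """Grain matching is exact over 100 seeded random placements with
        >= 5 mm spacing (centroids synthesised directly from the geometry,
        with sub-pixel detection noise)."""
        io = g.InteriorOrientation(0, 0, 3500)
        caml = g.CameraModel(io, g.ExteriorOrientation(0, 24, 350), image_size=(1760, 640))
        camr = g.CameraModel(io, g.ExteriorOrientation(80, 24, 350), image_size=(1760, 640))
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            pts = []
            while len(pts) < n:
                p = rng.uniform([5, 5], [75, 43])
                if all(np.hypot(*(p - q)) >= 5.0 for q in pts):
                    pts.append(p)
            obj = np.column_stack([pts, np.full(n, 0.9)])

            def regions_for(cam):
                rc = cam.raster_from_photo(cam.project(obj))
                rc = rc + rng.normal(0, 0.1, rc.shape)
                return [
                    seg.GrainRegion(label=i, area=1000, centroid=rc[i],
                                    boundary=np.zeros((1, 2), int))
                    for i in range(n)
                ]

            matches = edges.match_grains(regions_for(caml), regions_for(camr), caml, camr)
            assert len(matches) == n
            assert all(m.left_id == m.right_id for m in matches)

    def test_synthetic_scene_all_pairs_correct(self, small_scene, small_scene_rendered):
        left, right = small_scene_rendered
        regions = {}
        for side, img, cam in (
            ("l", left, small_scene.left_cam), ("r", right, small_scene.right_cam)
        ):
            _, mask = detect_circle_centers(img, small_scene.layout, return_mask=True)
            regions[side] = seg.segment_grains(img, exclude_mask=mask)
        matches = edges.match_grains(
            regions["l"], regions["r"], small_scene.left_cam, small_scene.right_cam
        )
        assert len(matches) == len(small_scene.grains)
        # verify each pair lands on the same true grain via the board plane
        truth = np.array([[gr.x, gr.y] for gr in small_scene.grains])
        by_label_l = {r.label: r for r in regions["l"]}
        by_label_r = {r.label: r for r in regions["r"]}
        for m in matches:
            rl, rr = by_label_l[m.left_id], by_label_r[m.right_id]
            gl = small_scene.left_cam.back_project_to_plane(
                small_scene.left_cam.photo_from_raster(rl.centroid), z=0.9
            )
            gr_ = small_scene.right_cam.back_project_to_plane(
                small_scene.right_cam.photo_from_raster(rr.centroid), z=0.9
            )
            il = np.linalg.norm(truth - gl[:2], axis=1).argmin()
            ir = np.linalg.norm(truth - gr_[:2], axis=1).argmin()
            assert il == ir

    def test_empty_right_list(self, small_scene, small_scene_rendered):
        left, _ = small_scene_rendered
        _, mask = detect_circle_centers(left, small_scene.layout, return_mask=True)
        regions = seg.segment_grains(left, exclude_mask=mask)
        assert edges.match_grains(
            regions, [], small_scene.left_cam, small_scene.right_cam
        ) == []

    def test_grain_missing_from_one_view_stays_unmatched(
        self, small_scene, small_scene_rendered
    ):
        left, right = small_scene_rendered
        regions = {}
        for side, img, cam in (
            ("l", left, small_scene.left_cam), ("r", right, small_scene.right_cam)
        ):
            _, mask = detect_circle_centers(img, small_scene.layout, return_mask=True)
            regions[side] = seg.segment_grains(img, exclude_mask=mask)
        dropped = regions["r"][1:]  # one grain invisible in the right image
        matches = edges.match_grains(
            regions["l"], dropped, small_scene.left_cam, small_scene.right_cam
        )
        assert len(matches) == len(small_scene.grains) - 1
        assert regions["r"][0].label not in {m.right_id for m in matches}
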