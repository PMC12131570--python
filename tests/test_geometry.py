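"""Axis fits, thinning, and angle computations."""

import numpy as np
import pytest
from skimage import measure

from phenokit.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    OutOfDomainError,
)
from phenokit.geometry import (
    KeypointTriple,
    angle_at_vertex,
    fit_ear_axis,
    flag_leaf_angle,
    ransac_major_axis,
    spikelet_angle,
    total_least_squares_line,
    zhang_suen_thin,
)
from phenokit.synth import _ellipse_mask_local


def angle_between(u, v):
    """Acute angle in degrees between two directions (sign-free)."""
    c = abs(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return np.degrees(np.arccos(np.clip(c, 0, 1)))


class TestRansacMajorAxis:
    def test_exact_diagonal_line(self):
        pts = np.asarray([[i, i] for i in range(30)], float)
        model = ransac_major_axis(pts, seed=0)
        assert np.allclose(model.direction, [np.sqrt(0.5), np.sqrt(0.5)], atol=1e-9)
        assert model.inlier_count == 30

    def test_rasterized_ellipse_orientation(self):
        theta = np.radians(25.0)
        m = np.zeros((200, 200), bool)
        rr, cc = _ellipse_mask_local((100, 100), 60, 20, theta, m.shape)
        m[rr, cc] = True
        pts = np.argwhere(m).astype(float)
        model = ransac_major_axis(pts, inlier_tol_px=2.0, seed=1)
        true_dir = [np.sin(theta), np.cos(theta)]  # (row, col)
        assert angle_between(model.direction, true_dir) <= 3.0

    def test_robust_to_uniform_outliers(self):
        rng = np.random.default_rng(11)
        t = rng.uniform(0, 100, 90)
        line = np.column_stack([20 + 0.8 * t, 10 + 0.6 * t])
        for seed in range(20):
            outliers = rng.uniform(0, 120, size=(10, 2))
            pts = np.vstack([line, outliers])
            model = ransac_major_axis(pts, inlier_tol_px=2.0, seed=seed)
            assert angle_between(model.direction, [0.8, 0.6]) <= 2.0

    def test_agrees_with_total_least_squares_when_clean(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 50, 100)
        pts = np.column_stack([t, 3 + 0.5 * t]) + rng.normal(0, 0.05, (100, 2))
        ransac = ransac_major_axis(pts, inlier_tol_px=1.0, seed=3)
        tls = total_least_squares_line(pts)
        assert angle_between(ransac.direction, tls.direction) <= 0.1

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            ransac_major_axis(np.ones((10, 2)), seed=0)


class TestFitEarAxis:
    def test_collinear_centers_zero_residual(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        axis = fit_ear_axis(pts, degree=1)
        assert axis.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_cubic_with_jitter_recovered_within_2px(self):
        rng = np.random.default_rng(4)
        y = np.linspace(0, 300, 24)
        x = 200 + 0.1 * (y - 150) + 3e-4 * (y - 150) ** 2 + 1e-6 * (y - 150) ** 3
        centers = np.column_stack([y, x]) + rng.normal(0, 1.0, (24, 2))
        axis = fit_ear_axis(centers, degree=3)
        true_pts = np.column_stack([y, x])
        # max distance from true curve points to the fitted curve
        u_dense = np.linspace(axis.domain[0], axis.domain[1], 2000)
        fitted = axis.evaluate(u_dense)
        d = np.linalg.norm(true_pts[:, None] - fitted[None], axis=-1).min(axis=1)
        assert d.max() <= 2.0

    def test_too_few_centers_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_ear_axis(np.zeros((3, 2)) + np.arange(3)[:, None], degree=3)


class TestZhangSuen:
    def test_bar_skeleton_one_pixel_thick(self):
        bar = np.zeros((20, 120), bool)
        bar[8:13, 10:110] = True
        skel = zhang_suen_thin(bar)
        assert skel.sum(axis=0).max() == 1
        assert (skel.sum(axis=0) > 0).sum() >= 90
        assert (skel <= bar).all()

    def test_single_pixel_fixed_point(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert np.array_equal(zhang_suen_thin(m), m)

    def test_annulus_topology_preserved(self):
        rr, cc = np.mgrid[0:100, 0:100]
        rho = np.hypot(rr - 50, cc - 50)
        ring = (rho >= 20) & (rho <= 35)
        skel = zhang_suen_thin(ring)
        # one connected skeleton curve enclosing one hole
        assert measure.label(skel, connectivity=2).max() == 1
        bg = measure.label(~skel, connectivity=1)
        assert bg.max() == 2  # outside + enclosed hole

    def test_subset_and_idempotent_on_random_blobs(self):
        from scipy import ndimage

        rng = np.random.default_rng(6)
        for _ in range(5):
            m = ndimage.binary_dilation(rng.random((60, 80)) > 0.97, iterations=3)
            skel = zhang_suen_thin(m)
            assert (skel <= m).all()
            assert np.array_equal(zhang_suen_thin(skel), skel)

    def test_agrees_structurally_with_reference_thinning(self):
        """Same-family algorithm in scikit-image yields skeletons of very
        similar size on random blobs (implementations differ in border
        staggering, so only structural agreement is expected)."""
        from scipy import ndimage
        from skimage.morphology import skeletonize

        rng = np.random.default_rng(7)
        for _ in range(5):
            m = ndimage.binary_dilation(rng.random((60, 80)) > 0.97, iterations=3)
            ours = zhang_suen_thin(m).sum()
            ref = skeletonize(m, method="zhang").sum()
            assert abs(ours - ref) / ref < 0.25


class TestAngles:
    @pytest.mark.parametrize(
        "vertex, p1, p2, expected",
        [
            ((0, 0), (1, 0), (0, 1), 90.0),
            ((0, 0), (1, 0), (1, 1), 45.0),
            ((2, 3), (5, 3), (-1, 3), 180.0),
        ],
    )
    def test_analytic_vertex_angles(self, vertex, p1, p2, expected):
        assert angle_at_vertex(vertex, p1, p2) == pytest.approx(expected, abs=1e-9)

    def test_matches_atan2_formulation_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            v, p1, p2 = rng.uniform(-100, 100, (3, 2))
            if np.allclose(p1, v) or np.allclose(p2, v):
                continue
            a1 = np.arctan2(*(p1 - v)[::-1])
            a2 = np.arctan2(*(p2 - v)[::-1])
            expected = np.degrees(abs((a1 - a2 + np.pi) % (2 * np.pi) - np.pi))
            assert angle_at_vertex(v, p1, p2) == pytest.approx(expected, abs=1e-9)

    def test_coincident_point_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            angle_at_vertex((0, 0), (0, 0), (1, 1))


class TestFlagLeafAngle:
    def test_node_mode_analytic(self):
        k = KeypointTriple(A=(0, -10), B=(0, 10), C=(0, 0), L=(10, 10))
        assert flag_leaf_angle(k) == pytest.approx(45.0)

    def test_leaf_along_stem_is_zero(self):
        k = KeypointTriple(A=(0, -10), B=(0, 10), C=(0, 0), L=(0, 5))
        assert flag_leaf_angle(k) == pytest.approx(0.0, abs=1e-9)

    def test_stem_axis_mode_orthogonal(self):
        k = KeypointTriple(A=(0, -10), B=(0, 10), C=(0, 0), L=(5, 0))
        assert flag_leaf_angle(k, mode="stem_axis_leaf") == pytest.approx(90.0)

    def test_missing_leaf_reference_rejected(self):
        k = KeypointTriple(A=(0, -10), B=(0, 10), C=(0, 0))
        with pytest.raises(InsufficientDataError):
            flag_leaf_angle(k)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        base = KeypointTriple(A=(0, -10), B=(1, 12), C=(0.5, 1), L=(9, 7))
        ref = flag_leaf_angle(base)
        for _ in range(10):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.asarray([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            shift = rng.uniform(-50, 50, 2)
            pts = {
                n: tuple(rot @ np.asarray(getattr(base, n)) + shift)
                for n in ("A", "B", "C", "L")
            }
            assert flag_leaf_angle(KeypointTriple(**pts)) == pytest.approx(ref, abs=1e-6)


class TestSpikeletAngle:
    @staticmethod
    def _straight_vertical_axis():
        centers = np.column_stack([np.linspace(0, 200, 12), np.full(12, 50.0)])
        return fit_ear_axis(centers, degree=3)

    def test_parallel_spikelet_zero_angle(self):
        from phenokit.geometry import LineModel

        axis = self._straight_vertical_axis()
        line = LineModel(point=(100, 50), direction=(1, 0))
        assert spikelet_angle(line, axis, (100, 50)) == pytest.approx(0.0, abs=1e-6)

    def test_analytic_40_degrees(self):
        from phenokit.geometry import LineModel

        axis = self._straight_vertical_axis()
        th = np.radians(40.0)
        line = LineModel(point=(100, 50), direction=(np.cos(th), np.sin(th)))
        assert spikelet_angle(line, axis, (100, 50)) == pytest.approx(40.0, abs=1e-6)

    def test_center_outside_domain_rejected(self):
        from phenokit.geometry import LineModel

        axis = self._straight_vertical_axis()
        line = LineModel(point=(0, 0), direction=(1, 0))
        with pytest.raises(OutOfDomainError):
            spikelet_angle(line, axis, (600, 50))

    def test_curved_axis_fixed_tangent_angle_recovered(self):
        """Spikelet axes drawn at 35 deg to the local tangent of a known
        cubic are recovered within 3 deg per spikelet."""
        from phenokit.geometry import LineModel

        y = np.linspace(60, 540, 18)
        x = 150 + 0.08 * (y - 300) + 2e-4 * (y - 300) ** 2 + 6e-7 * (y - 300) ** 3
        centers = np.column_stack([y, x])
        axis = fit_ear_axis(centers, degree=3)
        dx = 0.08 + 4e-4 * (y - 300) + 18e-7 * (y - 300) ** 2
        for i in range(18):
            tang = np.asarray([1.0, dx[i]])  # (row, col): dy=1, dcol=dx
            tang /= np.linalg.norm(tang)
            rot = np.radians(35.0)
            rotm = np.asarray([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
            line = LineModel(point=centers[i], direction=rotm @ tang)
            ang = spikelet_angle(line, axis, centers[i])
            assert abs(ang - 35.0) <= 3.0

    def test_rotation_invariance(self):
        from phenokit.geometry import LineModel

        rng = np.random.default_rng(10)
        y = np.linspace(0, 200, 12)
        centers = np.column_stack([y, 50 + 0.001 * y**2])
        line_dir = np.asarray([0.8, 0.6])
        center = centers[6]
        base = spikelet_angle(
            LineModel(point=center, direction=line_dir),
            fit_ear_axis(centers, 3),
            center,
        )
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.asarray([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            shift = rng.uniform(-100, 100, 2)
            c2 = centers @ rot.T + shift
            ang = spikelet_angle(
                LineModel(point=rot @ center + shift, direction=rot @ line_dir),
                fit_ear_axis(c2, 3),
                rot @ center + shift,
            )
            assert ang == pytest.approx(base, abs=1e-6)
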