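"""Geometric primitives: areas, centroids, axes, chords, lengths."""

import numpy as np
import pytest
import shapely
from scipy.integrate import quad
from shapely.geometry import Polygon

from avcoupling.geometry import (
    GeometryError,
    area_curve,
    centroid,
    chamber_area_curves,
    chamber_length,
    contour_length,
    cross_sectional_area,
    long_axis,
    max_transverse_diameter,
    polygon_area,
)
from avcoupling.io import ContourFrame, ContourSequence

from conftest import random_convex_polygon

SQUARE = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


def ellipse(a: float, b: float, n: int = 256, center=(0.0, 0.0), phase=0.0) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([a * np.cos(th) + center[0], b * np.sin(th) + center[1]])


def rasterized_area_cm2(points: np.ndarray, res: float = 0.05) -> float:
    """Grid-count area oracle: fraction of res-spaced grid points inside."""
    poly = Polygon(points)
    x0, y0, x1, y1 = poly.bounds
    xs = np.arange(x0 - res, x1 + res, res)
    ys = np.arange(y0 - res, y1 + res, res)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
    return inside.sum() * res * res / 100.0


class TestPolygonArea:
    def test_square(self):
        assert polygon_area(SQUARE) == pytest.approx(1.0, abs=1e-12)

    def test_regular_hexagon(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        hexagon = 10.0 * np.column_stack([np.cos(th), np.sin(th)])
        assert polygon_area(hexagon) == pytest.approx(3 * np.sqrt(3) / 2, rel=1e-12)

    def test_orientation_independent(self):
        assert polygon_area(SQUARE[::-1]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            poly = random_convex_polygon(rng)
            assert polygon_area(poly) == pytest.approx(
                rasterized_area_cm2(poly), rel=5e-3
            )

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0, 0], [10, 10]]),  # too few points
            np.array([[0, 0], [10, 10], [10, 0], [0, 10]]),  # bowtie
            np.array([[0, 0], [5, 0], [10, 0]]),  # collinear
        ],
    )
    def test_degenerate_rejected(self, bad):
        with pytest.raises(GeometryError):
            polygon_area(bad)


class TestCentroid:
    def test_square_symmetry(self):
        assert centroid(SQUARE) == pytest.approx([5.0, 5.0], abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        poly = random_convex_polygon(rng)
        shift = np.array([13.7, -4.2])
        assert centroid(poly + shift) == pytest.approx(centroid(poly) + shift, abs=1e-9)

    def test_l_shape_decomposition_oracle(self):
        # L = 20x10 rectangle + 10x10 square on top of its left half
        l_shape = np.array(
            [[0, 0], [20, 0], [20, 10], [10, 10], [10, 20], [0, 20]], dtype=float
        )
        # area-weighted mean of the two rectangles' centroids
        a1, c1 = 200.0, np.array([10.0, 5.0])
        a2, c2 = 100.0, np.array([5.0, 15.0])
        expected = (a1 * c1 + a2 * c2) / (a1 + a2)
        assert centroid(l_shape) == pytest.approx(expected, abs=1e-9)


class TestLongAxis:
    @staticmethod
    def _squares(c_lv, c_la):
        return SQUARE - 5.0 + np.asarray(c_lv), SQUARE - 5.0 + np.asarray(c_la)

    def test_axis_aligned(self):
        lv, la = self._squares([0, 0], [0, 40])
        direction, anchor = long_axis(lv, la)
        assert direction == pytest.approx([0.0, -1.0], abs=1e-12)
        assert anchor == pytest.approx([0.0, 40.0], abs=1e-9)

    def test_rotation_equivariance(self):
        lv, la = self._squares([0, 0], [0, 40])
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d0, _ = long_axis(lv, la)
        d1, _ = long_axis(lv @ rot.T, la @ rot.T)
        assert d1 == pytest.approx(rot @ d0, abs=1e-9)

    def test_coincident_centroids_rejected(self):
        lv, la = self._squares([0, 0], [0.5, 0.0])
        with pytest.raises(GeometryError, match="mm apart"):
            long_axis(lv, la)


class TestMaxTransverseDiameter:
    def test_ellipse_width(self):
        poly = ellipse(40.0, 20.0)
        # axis along the major direction -> max perpendicular chord = 2*20
        assert max_transverse_diameter(poly, [1.0, 0.0]) == pytest.approx(40.0, rel=1e-3)

    def test_circle_any_axis(self):
        poly = ellipse(15.0, 15.0)
        rng = np.random.default_rng(5)
        for _ in range(5):
            v = rng.normal(size=2)
            assert max_transverse_diameter(poly, v) == pytest.approx(30.0, rel=1e-3)

    @staticmethod
    def vertex_chord_oracle(points: np.ndarray, axis: np.ndarray) -> float:
        """Brute force: perpendicular chord span at every vertex station."""
        u = np.asarray(axis, float)
        u = u / np.hypot(*u)
        v = np.array([-u[1], u[0]])
        a, b = points @ u, points @ v
        a0, a1 = a, np.roll(a, -1)
        b0, b1 = b, np.roll(b, -1)
        best = 0.0
        for s in a:
            vs = []
            for i in range(len(points)):
                if (a0[i] - s) * (a1[i] - s) <= 0 and abs(a1[i] - a0[i]) > 1e-12:
                    t = (s - a0[i]) / (a1[i] - a0[i])
                    vs.append(b0[i] + t * (b1[i] - b0[i]))
                elif abs(a0[i] - s) <= 1e-12:
                    vs.append(b0[i])
            if len(vs) >= 2:
                best = max(best, max(vs) - min(vs))
        return best

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            poly = random_convex_polygon(rng, n_points=10)
            axis = rng.normal(size=2)
            got = max_transverse_diameter(poly, axis)
            want = self.vertex_chord_oracle(poly, axis)
            assert got == pytest.approx(want, rel=0.01)

    def test_no_intersection_rejected(self):
        with pytest.raises(GeometryError):
            max_transverse_diameter(SQUARE, [1.0, 0.0], step=20.0)


class TestCrossSectionalArea:
    def test_biplane_example(self):
        assert cross_sectional_area(30.0, 40.0) == pytest.approx(9.42, abs=0.01)

    def test_circular_limit(self):
        assert cross_sectional_area(25.0, 25.0, "biplane_ellipse") == pytest.approx(
            cross_sectional_area(d_4ch=25.0, mode="single_plane"), rel=1e-12
        )

    def test_errors(self):
        with pytest.raises(GeometryError):
            cross_sectional_area(30.0, -1.0)
        with pytest.raises(GeometryError):
            cross_sectional_area(30.0, None, "biplane_ellipse")
        with pytest.raises(GeometryError):
            cross_sectional_area(mode="single_plane")


class TestContourLength:
    def test_square_closed_vs_open(self):
        assert contour_length(SQUARE, closed=True) == pytest.approx(40.0)
        assert contour_length(SQUARE, closed=False) == pytest.approx(30.0)

    def test_half_ellipse_quadrature_oracle(self):
        a, b = 80.0, 20.0  # axial, transverse semiaxes
        phi = np.linspace(0, np.pi, 10_000)
        pts = np.column_stack([b * np.cos(phi), a * np.sin(phi)])
        got = contour_length(pts, closed=False)
        want, _ = quad(lambda t: np.hypot(b * np.sin(t), a * np.cos(t)), 0, np.pi)
        assert got == pytest.approx(want, rel=1e-3)


class TestInvariances:
    def test_rigid_motion(self):
        rng = np.random.default_rng(9)
        poly = random_convex_polygon(rng)
        axis = np.array([0.3, 1.0])
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = poly @ rot.T + np.array([40.0, -12.0])
        assert polygon_area(moved) == pytest.approx(polygon_area(poly), rel=1e-12)
        assert contour_length(moved, True) == pytest.approx(
            contour_length(poly, True), rel=1e-12
        )
        assert max_transverse_diameter(moved, rot @ axis) == pytest.approx(
            max_transverse_diameter(poly, axis), rel=5e-3
        )

    def test_scaling(self):
        rng = np.random.default_rng(10)
        poly = random_convex_polygon(rng)
        k = 1.7
        assert polygon_area(k * poly) == pytest.approx(k**2 * polygon_area(poly), rel=1e-12)
        assert contour_length(k * poly, True) == pytest.approx(
            k * contour_length(poly, True), rel=1e-12
        )
        assert chamber_length(k * poly, [0, 1]) == pytest.approx(
            k * chamber_length(poly, [0, 1]), rel=1e-12
        )


def _const_seq(chamber, points, n=12, view="4ch", closed=True):
    return ContourSequence(
        "T", view, chamber, closed, 1000.0, [ContourFrame(i, points.copy()) for i in range(n)]
    )


class TestAreaCurve:
    def test_constant_shape_constant_curve(self):
        lv = _const_seq("LV_endo", ellipse(20, 35, 64, center=(0, 30)))
        la = _const_seq("LA_endo", ellipse(15, 22, 64, center=(0, -30)))
        curve = area_curve(None, lv, None, la, mode="single_plane")
        assert np.allclose(curve.areas, curve.areas[0])
        assert curve.diameters_2ch is None
        assert curve.diameters_4ch is not None
        assert curve.times[-1] == pytest.approx(1000.0)

    def test_biplane_requires_both_views(self):
        lv = _const_seq("LV_endo", ellipse(20, 35, 64, center=(0, 30)))
        la = _const_seq("LA_endo", ellipse(15, 22, 64, center=(0, -30)))
        with pytest.raises(GeometryError):
            area_curve(None, lv, None, la, mode="biplane_ellipse")

    def test_frame_count_mismatch(self):
        lv = _const_seq("LV_endo", ellipse(20, 35, 64, center=(0, 30)), n=12)
        la = _const_seq("LA_endo", ellipse(15, 22, 64, center=(0, -30)), n=11)
        with pytest.raises(GeometryError, match="mismatch"):
            area_curve(None, lv, None, la, mode="single_plane")

    def test_zero_noise_subject_matches_truth_everywhere(self, zero_noise_subject):
        """Pipeline-measured area curves track ground truth within 0.5%."""
        from avcoupling.io import sequences_by_key

        idx = sequences_by_key(zero_noise_subject.sequences)
        lv_curve, la_curve = chamber_area_curves(
            idx[("2ch", "LV_endo")][0],
            idx[("2ch", "LA_endo")][0],
            idx[("4ch", "LV_endo")][0],
            idx[("4ch", "LA_endo")][0],
        )
        gt = zero_noise_subject.ground_truth
        assert np.allclose(lv_curve.areas, gt.true_lv_area_curve, rtol=5e-3)
        assert np.allclose(la_curve.areas, gt.true_la_area_curve, rtol=5e-3)
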