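"""Spherical-geometry kernel: circles, intersection points, Gauss-Bonnet."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sesarea.sphere_geom import (
    Arc,
    Cycle,
    SmallCircle,
    SphericalRegionBoundary,
    cap_area,
    circle_circle_points,
    gauss_bonnet_area,
    intersection_circle,
    spherical_triangle_excess,
)

ORIGIN = np.zeros(3)


class TestIntersectionCircle:
    def test_equal_spheres(self):
        # two 3.10 Å spheres 1.5 Å apart: plane at h = d/2, rho = sqrt(R^2-h^2)
        kind, circle, h = intersection_circle(
            ORIGIN, 3.10, np.array([1.5, 0, 0]), 3.10
        )
        assert kind == "circle"
        assert h == pytest.approx(0.75)
        rho = 3.10 * circle.sin_alpha
        assert rho == pytest.approx(math.sqrt(9.61 - 0.5625), abs=1e-12)
        assert circle.cos_alpha == pytest.approx(0.75 / 3.10)

    def test_unequal_spheres_plane_offset(self):
        kind, circle, h = intersection_circle(
            ORIGIN, 3.10, np.array([2.0, 0, 0]), 2.49
        )
        assert kind == "circle"
        assert h == pytest.approx((4.0 + 9.61 - 2.49**2) / 4.0)

    def test_external_tangency_is_absent(self):
        kind, circle, _ = intersection_circle(
            ORIGIN, 2.0, np.array([5.0, 0, 0]), 3.0
        )
        assert kind == "disjoint" and circle is None

    def test_engulfment_flags(self):
        kind, _, _ = intersection_circle(ORIGIN, 1.0, np.array([0.5, 0, 0]), 3.0)
        assert kind == "a_in_b"
        kind, _, _ = intersection_circle(ORIGIN, 3.0, np.array([0.5, 0, 0]), 1.0)
        assert kind == "b_in_a"

    def test_coincident_centers_degenerate(self):
        with pytest.raises(ValueError):
            intersection_circle(ORIGIN, 1.0, np.array([0.0, 0.0, 1e-9]), 2.0)


class TestCirclePairPoints:
    def test_orthogonal_great_circles(self):
        c1 = SmallCircle(np.array([0.0, 0.0, 1.0]), 0.0)
        c2 = SmallCircle(np.array([0.0, 1.0, 0.0]), 0.0)
        pts = circle_circle_points(c1, c2)
        assert len(pts) == 2
        assert np.allclose(pts[0], -pts[1])  # antipodal on the common line
        for p in pts:
            assert abs(p[1]) < 1e-12 and abs(p[2]) < 1e-12

    def test_disjoint_caps(self):
        c1 = SmallCircle(np.array([0.0, 0.0, 1.0]), math.cos(0.3))
        c2 = SmallCircle(np.array([0.0, 0.0, -1.0]), math.cos(0.3))
        assert circle_circle_points(c1, c2) == []

    def test_tangency_single_point(self):
        # axes separated by exactly alpha1 + alpha2
        a1, a2 = 0.4, 0.5
        axis2 = np.array([math.sin(a1 + a2), 0.0, math.cos(a1 + a2)])
        c1 = SmallCircle(np.array([0.0, 0.0, 1.0]), math.cos(a1))
        c2 = SmallCircle(axis2, math.cos(a2))
        pts = circle_circle_points(c1, c2)
        assert len(pts) == 1
        expected = np.array([math.sin(a1), 0.0, math.cos(a1)])
        assert np.allclose(pts[0], expected, atol=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_points_lie_on_both_circles_and_sphere(self, seed):
        rng = np.random.default_rng(seed)
        n1 = rng.normal(size=3)
        n1 /= np.linalg.norm(n1)
        n2 = rng.normal(size=3)
        n2 /= np.linalg.norm(n2)
        if abs(n1 @ n2) > 0.999:
            return
        c1 = SmallCircle(n1, rng.uniform(-0.9, 0.9))
        c2 = SmallCircle(n2, rng.uniform(-0.9, 0.9))
        for p in circle_circle_points(c1, c2):
            assert abs(np.linalg.norm(p) - 1.0) < 1e-9
            assert abs(p @ n1 - c1.cos_alpha) < 1e-9
            assert abs(p @ n2 - c2.cos_alpha) < 1e-9


class TestAreas:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(math.pi, 4 * math.pi), (math.pi / 2, 2 * math.pi), (math.pi / 3, math.pi)],
    )
    def test_cap_area(self, alpha, expected):
        assert cap_area(alpha) == pytest.approx(expected, abs=1e-12)

    def test_cap_area_domain(self):
        with pytest.raises(ValueError):
            cap_area(-0.1)

    def _free_cycle(self, axis, cos_alpha, side):
        circ = SmallCircle(np.asarray(axis, float), cos_alpha)
        return Cycle(
            arcs=[Arc(circle=circ, phi_start=0.0, sweep=2 * math.pi,
                      direction=side, side=side)]
        )

    def test_hemisphere(self):
        cyc = self._free_cycle([0, 0, 1], 0.0, +1)
        u = gauss_bonnet_area(SphericalRegionBoundary([cyc]))
        assert u == pytest.approx(2 * math.pi, abs=1e-12)

    def test_band_between_parallels(self):
        # region between colatitudes 60 and 120 degrees
        top = self._free_cycle([0, 0, 1.0], math.cos(math.pi / 3), -1)
        bottom = self._free_cycle([0, 0, -1.0], math.cos(math.pi / 3), -1)
        u = gauss_bonnet_area(SphericalRegionBoundary([top, bottom]))
        assert u == pytest.approx(2 * math.pi, abs=1e-12)

    def test_octant(self):
        # +++ octant bounded by three great circles, region on the left
        verts = [np.array([0, 0, 1.0]), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
        arcs = []
        for k in range(3):
            axis = np.cross(verts[k], verts[(k + 1) % 3])
            circ = SmallCircle(axis / np.linalg.norm(axis), 0.0)
            phi0 = circ.azimuth(verts[k])
            phi1 = circ.azimuth(verts[(k + 1) % 3])
            sweep = (phi1 - phi0) % (2 * math.pi)
            arcs.append(
                Arc(circle=circ, phi_start=phi0, sweep=sweep, direction=1,
                    side=1, start_vertex=k, end_vertex=(k + 1) % 3)
            )
        u = gauss_bonnet_area(SphericalRegionBoundary([Cycle(arcs=arcs)]))
        assert u == pytest.approx(math.pi / 2, abs=1e-10)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(min_value=0.1, max_value=3.0))
    def test_cap_complementarity(self, alpha):
        """Cap and complement partition the sphere: u + u' = 4*pi."""
        c = math.cos(alpha)
        inner = gauss_bonnet_area(
            SphericalRegionBoundary([self._free_cycle([0, 0, 1], c, +1)])
        )
        outer = gauss_bonnet_area(
            SphericalRegionBoundary([self._free_cycle([0, 0, 1], c, -1)])
        )
        assert inner == pytest.approx(cap_area(alpha), abs=1e-10)
        assert inner + outer == pytest.approx(4 * math.pi, abs=1e-10)

    def test_open_cycle_rejected(self):
        circ = SmallCircle(np.array([0.0, 0, 1.0]), 0.0)
        bad = Cycle(
            arcs=[
                Arc(circle=circ, phi_start=0.0, sweep=1.0, direction=1,
                    side=1, start_vertex=0, end_vertex=1),
                Arc(circle=circ, phi_start=2.0, sweep=1.0, direction=1,
                    side=1, start_vertex=2, end_vertex=0),
            ]
        )
        with pytest.raises(ValueError):
            gauss_bonnet_area(SphericalRegionBoundary([bad]))


def test_spherical_triangle_excess_octant():
    e = spherical_triangle_excess(
        np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    )
    assert e == pytest.approx(math.pi / 2, abs=1e-12)


def test_spherical_triangle_excess_degenerate():
    a = np.array([1.0, 0, 0])
    assert spherical_triangle_excess(a, a, np.array([0, 1.0, 0])) == 0.0
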