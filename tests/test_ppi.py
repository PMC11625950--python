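"""Probe-probe intersection resolution and probe-area algorithm."""

import math

import numpy as np
import pytest

from sesarea.io_mol import Atom, AtomSet
from sesarea.ppi import (
    GREEDY_CHECK_TOL,
    estimate_probe_area,
    exhaustive_probe_polygons,
    greedy_probe_polygons,
    probe_area,
    probe_neighbor_lists,
)
from sesarea.probes_tori import Probe
from sesarea.sphere_geom import cap_area

R_W = 1.4


def _probe_at(center, contact_dirs, pid=0):
    center = np.asarray(center, float)
    contacts = np.array([center + R_W * np.asarray(d) for d in contact_dirs])
    from sesarea.probes_tori import spherical_polygon_excess

    a_tr = spherical_polygon_excess(
        [np.asarray(d, float) for d in contact_dirs]
    ) * R_W**2
    return Probe(
        id=pid, center=center, atoms=(0, 1, 2), regions=(0, 1, 2),
        contacts=contacts, a_tr=a_tr,
    )


def _octant_probe():
    return _probe_at([0.0, 0.0, 0.0], [np.eye(3)[k] for k in range(3)])


class TestNeighborPredicate:
    def _probes(self, d):
        p0 = Probe(0, np.zeros(3), (0, 1, 2), (0, 1, 2), np.zeros((3, 3)))
        p1 = Probe(1, np.array([d, 0.0, 0.0]), (0, 1, 3), (0, 1, 3),
                   np.zeros((3, 3)))
        return [p0, p1]

    def test_just_under_diameter_are_neighbors(self):
        lists = probe_neighbor_lists(self._probes(2.79), R_W)
        assert lists[0] == [1] and lists[1] == [0]

    def test_exactly_diameter_not_neighbors(self):
        lists = probe_neighbor_lists(self._probes(2.80), R_W)
        assert lists[0] == [] and lists[1] == []

    def test_far_apart_not_neighbors(self):
        lists = probe_neighbor_lists(self._probes(3.50), R_W)
        assert lists[0] == []


class TestProbePolygons:
    def test_cap_inside_triangle_subtracted(self):
        """A PPI circle strictly inside the contact triangle becomes a hole:
        chi drops and a_gb = a_tr - cap_area * r_w^2."""
        probe = _octant_probe()
        m = np.ones(3) / math.sqrt(3)
        d = 2.6  # cap radius acos(d/2rw) ~ 21.7 deg, well inside the octant
        neighbor = probe.center + d * m
        arr, a_gb = greedy_probe_polygons(probe, [neighbor], R_W)
        assert len(arr.faces) == 1
        face = arr.faces[0]
        assert face.chi == 0  # polygon with a hole
        alpha = math.acos(d / (2 * R_W))
        expected = probe.a_tr - cap_area(alpha) * R_W**2
        assert a_gb == pytest.approx(expected, abs=1e-9)

    def test_cap_clipping_one_side(self):
        """A PPI cap crossing one triangle side: single cycle, area between
        0 and a_tr, agreeing with the grid estimate."""
        probe = _octant_probe()
        edge_dir = np.array([1.0, 1.0, 0]) / math.sqrt(2)
        neighbor = probe.center + 2.2 * edge_dir
        _arr, a_gb = greedy_probe_polygons(probe, [neighbor], R_W)
        est = estimate_probe_area(probe, [neighbor], R_W)
        assert 0.0 < a_gb < probe.a_tr
        assert abs(a_gb - est) < 0.2

    def test_caps_covering_triangle_give_zero(self):
        probe = _octant_probe()
        m = np.ones(3) / math.sqrt(3)
        neighbor = probe.center + 0.5 * m  # huge cap swallowing the octant
        filled = probe_area(probe, [neighbor], R_W)
        assert filled.a_p == 0.0

    def test_exhaustive_equals_greedy_when_greedy_accepted(self):
        probe = _octant_probe()
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            d = rng.uniform(1.0, 2.79)
            nbrs = [probe.center + d * v]
            _g, a_gb = greedy_probe_polygons(probe, nbrs, R_W)
            _e, a_ex = exhaustive_probe_polygons(probe, nbrs, R_W)
            assert a_gb == pytest.approx(a_ex, abs=1e-9)

    def test_two_overlapping_caps_cross_hole(self):
        """Two PPI circles overlapping inside the triangle: the union hole is
        removed exactly once (checked against the grid oracle)."""
        probe = _octant_probe()
        m = np.ones(3) / math.sqrt(3)
        e = np.array([1.0, -1.0, 0]) / math.sqrt(2)
        nbrs = [
            probe.center + 2.6 * (m + 0.12 * e) / np.linalg.norm(m + 0.12 * e),
            probe.center + 2.6 * (m - 0.12 * e) / np.linalg.norm(m - 0.12 * e),
        ]
        filled = probe_area(_octant_probe(), nbrs, R_W)
        est = estimate_probe_area(probe, nbrs, R_W)
        assert abs(filled.a_p - est) < 0.2
        assert filled.a_p < probe.a_tr - cap_area(math.acos(2.6 / 2.8)) * R_W**2


class TestProbeAreaAlgorithm:
    def test_isolated_probe_keeps_triangle_area(self):
        probe = _octant_probe()
        filled = probe_area(probe, [], R_W)
        assert filled.a_p == pytest.approx(probe.a_tr)
        assert filled.a_gb is None and filled.a_es is None

    def test_bounds_and_gate(self):
        probe = _octant_probe()
        rng = np.random.default_rng(7)
        for _ in range(30):
            k = rng.integers(1, 4)
            nbrs = []
            for _ in range(k):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                nbrs.append(probe.center + rng.uniform(0.8, 2.79) * v)
            filled = probe_area(_octant_probe(), nbrs, R_W)
            assert 0.0 <= filled.a_p <= filled.a_tr + 1e-9
            if filled.a_gb is not None and filled.a_es is not None:
                if abs(filled.a_gb - filled.a_es) < GREEDY_CHECK_TOL:
                    assert filled.a_p == pytest.approx(filled.a_gb, abs=1e-9)

    def test_monotone_under_added_ppis(self):
        """Adding intersecting probes never increases a probe's area."""
        rng = np.random.default_rng(3)
        nbrs = []
        for _ in range(6):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            nbrs.append(np.zeros(3) + rng.uniform(1.2, 2.7) * v)
        prev = None
        for k in range(len(nbrs) + 1):
            filled = probe_area(_octant_probe(), nbrs[:k], R_W)
            if prev is not None:
                assert filled.a_p <= prev + 1e-9
            prev = filled.a_p

    def test_cluster_probes_greedy_vs_exhaustive(self, cluster_results):
        """On real enumerated probes, greedy-accepted areas equal the
        exhaustive result."""
        checked = 0
        for _seed, atoms, result in cluster_results:
            lists = probe_neighbor_lists(result.probes, atoms.r_w)
            by_id = {p.id: p for p in result.probes}
            for p in result.probes:
                if not lists[p.id] or checked >= 40:
                    continue
                nbrs = [by_id[m].center for m in lists[p.id]]
                if p.a_gb is None or p.a_es is None:
                    continue
                if abs(p.a_gb - p.a_es) < GREEDY_CHECK_TOL:
                    _e, a_ex = exhaustive_probe_polygons(p, nbrs, atoms.r_w)
                    assert p.a_gb == pytest.approx(a_ex, abs=1e-8)
                    checked += 1
        assert checked > 5
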