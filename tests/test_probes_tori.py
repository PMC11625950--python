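"""Probe enumeration, trilateration, toroidal patch areas."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

from sesarea.fixtures import diatomic, spindle_pair, tetrahedron, triple
from sesarea.io_mol import Atom, AtomSet
from sesarea.pipeline import compute
from sesarea.probes_tori import (
    pair_torus_geometry,
    probe_positions,
    toroidal_patch_area,
)


def _quad_torus(r_c, phi, t_lo, t_hi, r_w):
    """1-D quadrature oracle for the surface-of-revolution integral,
    truncated at the spindle cusp when r_c < r_w."""
    def rho(t):
        return r_c - r_w * math.cos(t)

    if r_c < r_w:
        t_c = math.acos(r_c / r_w)
        total = 0.0
        lo, hi = t_lo, min(t_hi, -t_c)
        if hi > lo:
            total += quad(rho, lo, hi)[0]
        lo, hi = max(t_lo, t_c), t_hi
        if hi > lo:
            total += quad(rho, lo, hi)[0]
        return phi * r_w * total
    return phi * r_w * quad(rho, t_lo, t_hi)[0]


class TestProbePositions:
    def test_equilateral_triple_mirror_pair(self):
        atoms, manifest = triple(s=4.0)
        cands = probe_positions(0, 1, 2, atoms)
        assert len(cands) == 2
        z = manifest["probe_height"]
        got = sorted(round(c[2], 6) for c in cands)
        assert got == [round(-z, 6), round(z, 6)]
        # closed form: height = sqrt(R^2 - s^2/3)
        assert z == pytest.approx(math.sqrt(3.1**2 - 16.0 / 3.0), abs=1e-12)

    def test_too_far_apart_no_solution(self):
        # equilateral side beyond sqrt(3)*R = 5.369: circumradius > R
        s = 5.4
        atoms = AtomSet(
            [
                Atom(0, "C", np.array([0.0, 0, 0]), 1.7),
                Atom(1, "C", np.array([s, 0, 0]), 1.7),
                Atom(2, "C", np.array([s / 2, s * math.sqrt(3) / 2, 0]), 1.7),
            ]
        )
        assert probe_positions(0, 1, 2, atoms) == []

    def test_tetrahedron_inner_candidates_blocked(self):
        """At side 4.0 the inward-facing probe of each face sits inside the
        opposite atom's expanded sphere and must be discarded."""
        atoms, _ = tetrahedron(s=4.0)
        for trio in itertools.combinations(range(4), 3):
            cands = probe_positions(*trio, atoms)
            assert len(cands) == 1  # outward survivor only

    def test_collinear_centers_rejected(self):
        atoms = AtomSet(
            [
                Atom(0, "C", np.array([0.0, 0, 0]), 1.7),
                Atom(1, "C", np.array([2.0, 0, 0]), 1.7),
                Atom(2, "C", np.array([4.0, 0, 0]), 1.7),
            ]
        )
        assert probe_positions(0, 1, 2, atoms) == []


class TestEnumeration:
    def test_diatomic_no_probes_one_free_torus(self, diatomic_result):
        _atoms, manifest, result = diatomic_result
        assert result.n_probes == 0
        assert result.n_tori == 1
        patch = result.tori[0]
        assert patch.is_free and patch.phi == pytest.approx(2 * math.pi)
        assert patch.r_c == pytest.approx(manifest["r_c"], abs=1e-12)

    def test_triple_probe_pair_and_patches(self, triple_result):
        _atoms, manifest, result = triple_result
        assert result.n_probes == manifest["n_probes"] == 2
        # one accessible saddle per atom pair, wrapped between both probes
        assert result.n_tori == 3
        for patch in result.tori:
            assert not patch.is_free
            assert set(patch.probes) == {0, 1}

    def test_enumeration_matches_trilateration(self, cluster_results):
        """Vertex-clustered probes equal brute-force trilateration over all
        atom triples plus the containment filter."""
        for _seed, atoms, result in cluster_results:
            expected = []
            for trio in itertools.combinations(range(len(atoms)), 3):
                expected.extend(probe_positions(*trio, atoms))
            got = sorted(tuple(np.round(p.center, 5)) for p in result.probes)
            want = sorted(tuple(np.round(c, 5)) for c in expected)
            assert got == want

    def test_probe_tangency_residuals(self, cluster_results):
        for _seed, atoms, result in cluster_results:
            R = atoms.expanded_radii
            for p in result.probes:
                for a in p.atoms:
                    d = np.linalg.norm(p.center - atoms.centers[a])
                    assert abs(d - R[a]) < 1e-6

    def test_mirror_symmetry_of_probe_set(self, triple_result):
        """The triple has a z=0 mirror plane; so must its probes."""
        _atoms, _manifest, result = triple_result
        centers = sorted(tuple(np.round(p.center, 8)) for p in result.probes)
        mirrored = sorted(
            tuple(np.round(p.center * np.array([1, 1, -1]), 8))
            for p in result.probes
        )
        assert centers == mirrored

    def test_wrap_angles_partition_accessible_circle(self, cluster_results):
        """Per atom pair the patch wrap angles sum to the accessible angular
        measure, never exceeding the full circle."""
        for _seed, _atoms, result in cluster_results:
            by_pair = {}
            for patch in result.tori:
                by_pair.setdefault(patch.atoms, 0.0)
                by_pair[patch.atoms] += patch.phi
            for total in by_pair.values():
                assert total <= 2 * math.pi + 1e-9


class TestToroidalArea:
    def test_zero_wrap_zero_area(self):
        assert toroidal_patch_area(3.0, 0.0, -0.5, 0.5, 1.4) == 0.0

    def test_free_regular_torus_vs_quadrature(self, diatomic_result):
        atoms, _manifest, result = diatomic_result
        patch = result.tori[0]
        r_c, t_i, t_j, _ = pair_torus_geometry(0, 1, atoms)
        oracle = _quad_torus(r_c, 2 * math.pi, t_i, t_j, atoms.r_w)
        assert patch.a_t == pytest.approx(oracle, abs=1e-6)
        assert not patch.spindle

    def test_spindle_torus_vs_quadrature(self, spindle_result):
        atoms, _manifest, result = spindle_result
        patch = result.tori[0]
        assert patch.spindle
        r_c, t_i, t_j, _ = pair_torus_geometry(0, 1, atoms)
        assert r_c < atoms.r_w
        oracle = _quad_torus(r_c, 2 * math.pi, t_i, t_j, atoms.r_w)
        assert patch.a_t == pytest.approx(oracle, abs=1e-6)

    def test_cluster_patches_vs_quadrature(self, cluster_results):
        for _seed, atoms, result in cluster_results:
            for patch in result.tori[:50]:
                i, j = patch.atoms
                r_c, t_i, t_j, _ = pair_torus_geometry(i, j, atoms)
                oracle = _quad_torus(r_c, patch.phi, t_i, t_j, atoms.r_w)
                assert patch.a_t == pytest.approx(oracle, abs=1e-6)


class TestSphericalTriangleArea:
    def test_octant_probe_area(self):
        from sesarea.probes_tori import spherical_polygon_excess

        dirs = [np.eye(3)[k] for k in range(3)]
        assert spherical_polygon_excess(dirs) * 1.4**2 == pytest.approx(
            (math.pi / 2) * 1.96, abs=1e-9
        )

    def test_degenerate_contacts_zero(self):
        from sesarea.probes_tori import spherical_polygon_excess

        a = np.array([1.0, 0, 0])
        assert spherical_polygon_excess([a, a, np.array([0, 1.0, 0])]) == 0.0

    def test_triple_probe_triangle_vs_grid(self, triple_result):
        """Isolated probe area equals its Shrake-Rupley estimate closely."""
        from sesarea.ppi import estimate_probe_area

        atoms, _manifest, result = triple_result
        for p in result.probes:
            est = estimate_probe_area(p, [], atoms.r_w)
            assert abs(p.a_tr - est) < 0.2
            assert p.a_p == pytest.approx(p.a_tr)  # isolated: a_p = a_tr
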