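"""Fixed probes and toroidal patches.

A *fixed probe* is a solvent sphere of radius ``r_w`` simultaneously tangent
to three atoms.  Its center is at distance ``r_t + r_w`` from each defining
atom ``t`` — exactly the description of a boundary vertex of the SAS
regions, scaled from the unit sphere to the expanded sphere.  Probes are
therefore enumerated by clustering the SAS boundary vertices of all atoms:
each spatial cluster (three coincident vertices, one per participating
atom) is one probe.  This is cross-checked on small fixtures against direct
trilateration over all atom triples.

A *toroidal patch* is the saddle surface swept by the probe arc while the
probe center runs along one accessible arc of the intersection circle of
two expanded spheres.  Patches are bounded by two probes, or form a full
torus when the circle is free on both atoms.  When the probe-center circle
radius ``r_c`` drops below ``r_w`` the torus self-intersects (spindle) and
the patch is truncated at the cusp angle ``arccos(r_c / r_w)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .arrangement import GeometryError
from .io_mol import AtomSet
from .sas_regions import RegionSet
from .sphere_geom import (
    EPS_PT,
    _normalize,
    spherical_triangle_excess,
)


@dataclass
class Probe:
    """A probe sphere tangent to three (rarely four) atoms."""

    id: int
    center: np.ndarray
    atoms: tuple[int, ...]          # 0-based, sorted
    regions: tuple[int, ...]        # region ids, aligned with atoms
    contacts: np.ndarray            # (k, 3) contact points on the probe sphere
    a_tr: float = 0.0               # isolated (spherical polygon) area, Å²
    a_gb: Optional[float] = None    # greedy Gauss-Bonnet area, Å²
    a_es: Optional[float] = None    # Shrake-Rupley estimate, Å²
    a_p: Optional[float] = None     # final probe area, Å²
    component: Optional[int] = None
    used_exhaustive: bool = False

    @property
    def is_isolated(self) -> bool:
        return self.a_gb is None and self.a_es is None


@dataclass
class ToroidalPatch:
    """A saddle patch between two atoms, bounded by two probes (or free)."""

    id: int
    atoms: tuple[int, int]
    regions: tuple[int, int]
    probes: Optional[tuple[int, int]]   # None for a free (full) torus
    r_c: float                          # probe-center circle radius, Å
    phi: float                          # wrap angle about the atom-atom axis
    theta_range: tuple[float, float]    # contact angles about the probe circle
    spindle: bool
    a_t: float = 0.0                    # patch area, Å²
    component: Optional[int] = None

    @property
    def is_free(self) -> bool:
        return self.probes is None


# ---------------------------------------------------------------------------
# probe enumeration

def probe_positions(
    i: int, j: int, k: int, atoms: AtomSet
) -> list[np.ndarray]:
    """Centers of probes tangent to atoms i, j, k by trilateration.

    Candidates whose center lies strictly inside any other atom's expanded
    sphere are discarded.  Collinear atom centers give no solution.
    """
    centers = atoms.centers
    R = atoms.expanded_radii
    p1, p2, p3 = centers[i], centers[j], centers[k]
    r1, r2, r3 = R[i], R[j], R[k]
    ex = p2 - p1
    d = float(np.linalg.norm(ex))
    if d < EPS_PT:
        raise ValueError("coincident atom centers")
    ex = ex / d
    v = p3 - p1
    iv = float(ex @ v)
    ey = v - iv * ex
    ny = float(np.linalg.norm(ey))
    if ny < 1e-9:
        return []  # collinear centers
    ey = ey / ny
    ez = np.cross(ex, ey)
    x = (r1 * r1 - r2 * r2 + d * d) / (2.0 * d)
    y = (r1 * r1 - r3 * r3 + iv * iv + ny * ny - 2.0 * x * iv) / (2.0 * ny)
    z2 = r1 * r1 - x * x - y * y
    if z2 <= 0.0:
        return []
    z = math.sqrt(z2)
    out = []
    for sign in (1.0, -1.0):
        c = p1 + x * ex + y * ey + sign * z * ez
        blocked = False
        for m in range(len(atoms)):
            if m in (i, j, k):
                continue
            if float(np.linalg.norm(c - centers[m])) < R[m] - EPS_PT:
                blocked = True
                break
        if not blocked:
            out.append(c)
    return out


def _ordered_contact_dirs(dirs: list[np.ndarray]) -> list[int]:
    """Order contact directions counter-clockwise about their mean."""
    m = np.sum(dirs, axis=0)
    nm = float(np.linalg.norm(m))
    if nm < 1e-9:
        m = np.cross(dirs[1] - dirs[0], dirs[2] - dirs[0])
        nm = float(np.linalg.norm(m))
        if nm < 1e-12:
            return list(range(len(dirs)))
    m = m / nm
    e1, e2 = None, None
    from .sphere_geom import perpendicular_frame

    e1, e2 = perpendicular_frame(m)
    ang = [math.atan2(float(d @ e2), float(d @ e1)) for d in dirs]
    return sorted(range(len(dirs)), key=lambda q: ang[q])


def spherical_polygon_excess(dirs: list[np.ndarray]) -> float:
    """Solid angle of the spherical polygon with the given ordered vertices
    (great-circle sides, counter-clockwise order)."""
    n = len(dirs)
    if n < 3:
        return 0.0
    if n == 3:
        return spherical_triangle_excess(*dirs)
    total = 0.0
    for k in range(1, n - 1):
        total += spherical_triangle_excess(dirs[0], dirs[k], dirs[k + 1])
    return total


def enumerate_probes(
    atoms: AtomSet, region_set: RegionSet
) -> tuple[list[Probe], dict[tuple[int, int], int]]:
    """Cluster SAS boundary vertices into probes.

    Returns the probe list and a map ``(atom, local vertex id) -> probe id``.
    """
    entries: list[tuple[int, int, int, np.ndarray]] = []  # atom, vid, region, pos
    for surface in region_set.surfaces:
        if surface.arrangement is None:
            continue
        center = atoms.centers[surface.atom]
        for vid, region_id in surface.vertex_region.items():
            pos = surface.vertex_world(vid, center)
            entries.append((surface.atom, vid, region_id, pos))

    probes: list[Probe] = []
    vertex_map: dict[tuple[int, int], int] = {}
    if not entries:
        return probes, vertex_map

    positions = np.array([e[3] for e in entries])
    tree = cKDTree(positions)
    pairs = tree.query_pairs(EPS_PT)
    parent = list(range(len(entries)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    clusters: dict[int, list[int]] = {}
    for idx in range(len(entries)):
        clusters.setdefault(find(idx), []).append(idx)

    r_w = atoms.r_w
    centers = atoms.centers
    R = atoms.expanded_radii
    for members in sorted(clusters.values(), key=lambda ms: min(ms)):
        atom_entries: dict[int, tuple[int, int]] = {}
        for idx in members:
            atom_i, vid, region_id, _pos = entries[idx]
            atom_entries.setdefault(atom_i, (vid, region_id))
        if len(atom_entries) < 3:
            raise GeometryError(
                f"probe vertex touched by only {len(atom_entries)} atoms"
            )
        center = positions[members].mean(axis=0)
        atom_ids = tuple(sorted(atom_entries))
        region_ids = tuple(atom_entries[a][1] for a in atom_ids)
        contacts = []
        for a in atom_ids:
            resid = abs(float(np.linalg.norm(center - centers[a])) - R[a])
            if resid > 10 * EPS_PT:
                raise GeometryError(
                    f"probe tangency residual {resid:.2e} Å at atom {a + 1}"
                )
            contacts.append(center + r_w * _normalize(centers[a] - center))
        pid = len(probes)
        dirs = [_normalize(c - center) for c in contacts]
        order = _ordered_contact_dirs(dirs)
        atom_ids = tuple(atom_ids[q] for q in order)
        region_ids = tuple(region_ids[q] for q in order)
        contacts = np.array([contacts[q] for q in order])
        dirs = [dirs[q] for q in order]
        # enforce counter-clockwise orientation seen from outside
        m = _normalize(np.sum(dirs, axis=0)) if float(
            np.linalg.norm(np.sum(dirs, axis=0))
        ) > 1e-9 else dirs[0]
        if float(np.cross(dirs[0], dirs[1]) @ m) < 0.0:
            atom_ids = tuple(reversed(atom_ids))
            region_ids = tuple(reversed(region_ids))
            contacts = contacts[::-1].copy()
            dirs = dirs[::-1]
        a_tr = spherical_polygon_excess(dirs) * r_w * r_w
        probe = Probe(
            id=pid,
            center=center,
            atoms=atom_ids,
            regions=region_ids,
            contacts=contacts,
            a_tr=a_tr,
        )
        probes.append(probe)
        for idx in members:
            atom_i, vid, _r, _p = entries[idx]
            vertex_map[(atom_i, vid)] = pid
    return probes, vertex_map


# ---------------------------------------------------------------------------
# toroidal patches

def pair_torus_geometry(
    i: int, j: int, atoms: AtomSet
) -> tuple[float, float, float, float]:
    """Return (r_c, theta_i, theta_j, d) for the atom pair's torus.

    ``r_c`` is the probe-center circle radius; ``theta`` angles are measured
    on the probe circle from the direction pointing at the pair axis, with
    atom ``i``'s contact at ``theta_i <= 0`` and atom ``j``'s at
    ``theta_j >= 0`` (for a circle plane between the two atoms).
    """
    centers = atoms.centers
    R = atoms.expanded_radii
    d = float(np.linalg.norm(centers[j] - centers[i]))
    h = (d * d + R[i] * R[i] - R[j] * R[j]) / (2.0 * d)
    rc2 = R[i] * R[i] - h * h
    if rc2 <= 0.0:
        raise GeometryError(f"atoms {i + 1},{j + 1} do not support a torus")
    r_c = math.sqrt(rc2)
    theta_i = -math.atan2(h, r_c)
    theta_j = math.atan2(d - h, r_c)
    return r_c, theta_i, theta_j, d


def toroidal_patch_area(
    r_c: float,
    phi: float,
    theta_lo: float,
    theta_hi: float,
    r_w: float,
) -> float:
    """Area of a toroidal patch as a surface of revolution.

    The probe-circle point at angle ``theta`` sits at distance
    ``r_c - r_w*cos(theta)`` from the axis, so the patch area is
    ``phi * [r_c*r_w*theta - r_w^2*sin(theta)]`` over the contact-angle
    range; for a spindle torus (``r_c < r_w``) the self-intersecting piece
    ``|theta| < arccos(r_c/r_w)`` is removed.
    """
    if phi < 0.0 or theta_hi < theta_lo:
        raise ValueError("invalid toroidal patch parameters")

    def anti(theta: float) -> float:
        return r_c * r_w * theta - r_w * r_w * math.sin(theta)

    intervals: list[tuple[float, float]]
    if r_c < r_w:
        theta_c = math.acos(r_c / r_w)
        intervals = []
        lo, hi = theta_lo, min(theta_hi, -theta_c)
        if hi > lo:
            intervals.append((lo, hi))
        lo, hi = max(theta_lo, theta_c), theta_hi
        if hi > lo:
            intervals.append((lo, hi))
    else:
        intervals = [(theta_lo, theta_hi)]
    area = phi * sum(anti(b) - anti(a) for a, b in intervals)
    if area < -1e-8:
        raise GeometryError(f"negative toroidal area {area:.3e}")
    return max(area, 0.0)


def enumerate_tori(
    atoms: AtomSet,
    region_set: RegionSet,
    probes: list[Probe],
    vertex_map: dict[tuple[int, int], int],
) -> list[ToroidalPatch]:
    """One patch per accessible arc of every atom-pair circle.

    The accessible arcs on the two atoms of a pair are the same spatial
    curves; they are matched by probe pair (or free/free) and checked for
    count consistency.
    """
    # collect boundary arcs per atom pair
    pair_arcs: dict[tuple[int, int], dict[int, list]] = {}
    for surface in region_set.surfaces:
        if surface.arrangement is None:
            continue
        i = surface.atom
        center = atoms.centers[i]
        for region in surface.regions:
            face = surface.arrangement.faces[region.face_index]
            for cycle in face.cycles:
                for arc in cycle.arcs:
                    j = arc.tag
                    key = (min(i, j), max(i, j))
                    sides = pair_arcs.setdefault(key, {})
                    sides.setdefault(i, []).append((region.id, arc, center))
    patches: list[ToroidalPatch] = []
    r_w = atoms.r_w
    R = atoms.expanded_radii
    for (i, j), sides in sorted(pair_arcs.items()):
        arcs_i = sides.get(i, [])
        arcs_j = sides.get(j, [])
        if len(arcs_i) != len(arcs_j):
            raise GeometryError(
                f"asymmetric arc counts on pair {i + 1},{j + 1}: "
                f"{len(arcs_i)} vs {len(arcs_j)}"
            )
        if not arcs_i:
            continue
        r_c, theta_i, theta_j, _d = pair_torus_geometry(i, j, atoms)
        spindle = r_c < r_w

        def arc_mid_world(entry):
            region_id, arc, center = entry
            atom = region_set.regions[region_id].atom
            return center + R[atom] * arc.midpoint

        used_j = set()
        for entry_i in arcs_i:
            region_i, arc_i, center_i = entry_i
            if arc_i.is_full_circle:
                frees = [
                    q for q, e in enumerate(arcs_j)
                    if q not in used_j and e[1].is_full_circle
                ]
                if not frees:
                    raise GeometryError(
                        f"unmatched free torus on pair {i + 1},{j + 1}"
                    )
                best = frees[0]
            else:
                mid_i = arc_mid_world(entry_i)
                best, best_d = None, None
                for q, entry_j in enumerate(arcs_j):
                    if q in used_j or entry_j[1].is_full_circle:
                        continue
                    dd = float(np.linalg.norm(arc_mid_world(entry_j) - mid_i))
                    if best_d is None or dd < best_d:
                        best, best_d = q, dd
                if best is None or best_d > 1e-5:
                    raise GeometryError(
                        f"unmatched toroidal arc on pair {i + 1},{j + 1}"
                    )
            used_j.add(best)
            region_j = arcs_j[best][0]
            if arc_i.is_full_circle:
                probe_pair = None
                phi = 2.0 * math.pi
            else:
                pa = vertex_map[(i, arc_i.start_vertex)]
                pb = vertex_map[(i, arc_i.end_vertex)]
                probe_pair = (pa, pb)
                phi = arc_i.sweep
            a_t = toroidal_patch_area(r_c, phi, theta_i, theta_j, r_w)
            patches.append(
                ToroidalPatch(
                    id=len(patches),
                    atoms=(i, j),
                    regions=(region_i, region_j),
                    probes=probe_pair,
                    r_c=r_c,
                    phi=phi,
                    theta_range=(theta_i, theta_j),
                    spindle=spindle,
                    a_t=a_t,
                )
            )
    return patches
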