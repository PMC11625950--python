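"""Probe-probe intersection (PPI) resolution and probe areas.

Two probes intersect when their centers are closer than the probe diameter
(2.8 Å for a 1.4 Å water probe).  Each intersection clips the intersecting
neighbor's cap out of the probe's spherical contact triangle.  The probe
polygons that survive are found with the same arrangement machinery used
for SAS regions: the triangle sides and the PPI circles form the
constraints, greedily stitched boundary cycles give the Gauss-Bonnet area
``a_gb``, a deterministic Shrake-Rupley estimate ``a_es`` guards the greedy
result, and on disagreement (>= 1e-2 Å²) an exhaustive depth-first cycle
search with interior-sample membership tests recomputes the polygon set.

PPIs are resolved against *all* probes of the molecule, regardless of the
surface component they belong to — an exterior probe clipped by a cavity
probe is clipped all the same.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .arrangement import Arrangement, Constraint, GeometryError, build_faces
from .probes_tori import Probe
from .shrake_rupley import DEFAULT_LEVEL, grid_weights, unit_sphere_grid
from .sphere_geom import SmallCircle, _normalize

#: Gauss-Bonnet vs Shrake-Rupley agreement gate (Å²)
GREEDY_CHECK_TOL = 1e-2


def probe_neighbor_lists(
    probes: Sequence[Probe], r_w: float
) -> dict[int, list[int]]:
    """Symmetric lists of intersecting probes (center distance < 2*r_w)."""
    lists: dict[int, list[int]] = {p.id: [] for p in probes}
    if len(probes) < 2:
        return lists
    centers = np.array([p.center for p in probes])
    tree = cKDTree(centers)
    # query_pairs uses <=; shave an epsilon to keep the predicate strict
    for a, b in sorted(tree.query_pairs(2.0 * r_w * (1.0 - 1e-12))):
        d = float(np.linalg.norm(centers[a] - centers[b]))
        if d < 2.0 * r_w:
            lists[probes[a].id].append(probes[b].id)
            lists[probes[b].id].append(probes[a].id)
    return lists


def probe_constraints(
    probe: Probe,
    neighbor_centers: Sequence[np.ndarray],
    r_w: float,
) -> list[Constraint]:
    """Arrangement constraints on the probe's unit sphere: inside the contact
    polygon, outside every intersecting probe."""
    cons: list[Constraint] = []
    dirs = [
        _normalize(np.asarray(c) - probe.center) for c in probe.contacts
    ]
    k = len(dirs)
    for idx in range(k):
        a, b = dirs[idx], dirs[(idx + 1) % k]
        axis = np.cross(a, b)
        norm = float(np.linalg.norm(axis))
        if norm < 1e-12:
            raise GeometryError("degenerate probe contact polygon")
        cons.append(
            Constraint(
                circle=SmallCircle(axis=axis / norm, cos_alpha=0.0),
                side=+1,
                tag=("side", idx),
            )
        )
    side_axes = np.array([c.circle.axis for c in cons])
    caps: list[tuple[np.ndarray, float, int]] = []  # axis, cos_alpha, tag
    for m, c_m in enumerate(neighbor_centers):
        delta = np.asarray(c_m) - probe.center
        d = float(np.linalg.norm(delta))
        if d >= 2.0 * r_w or d < 1e-9:
            continue
        caps.append((delta / d, d / (2.0 * r_w), m))
    # drop caps that cannot touch the contact polygon (entirely in the
    # forbidden half of some side) — they change nothing but cost O(n^2)
    kept: list[tuple[np.ndarray, float, int]] = []
    for axis, cosa, m in caps:
        sina = math.sqrt(max(0.0, 1.0 - cosa * cosa))
        if np.any(side_axes @ axis < -sina - 1e-12):
            continue
        kept.append((axis, cosa, m))
    # drop caps engulfed by a larger kept cap (their exclusion is implied)
    kept.sort(key=lambda t: t[1])  # ascending cos_alpha = descending size
    final: list[tuple[np.ndarray, float, int]] = []
    for axis, cosa, m in kept:
        redundant = False
        for axis2, cosa2, _m2 in final:
            sep = math.acos(min(1.0, max(-1.0, float(axis @ axis2))))
            if sep + math.acos(cosa) <= math.acos(cosa2) - 1e-9:
                redundant = True
                break
        if not redundant:
            final.append((axis, cosa, m))
    for axis, cosa, m in final:
        cons.append(
            Constraint(
                circle=SmallCircle(axis=axis, cos_alpha=cosa),
                side=-1,
                tag=("ppi", m),
            )
        )
    return cons


def _polygon_area(arr: Arrangement, r_w: float) -> float:
    return sum(f.area_sr for f in arr.faces) * r_w * r_w


def greedy_probe_polygons(
    probe: Probe, neighbor_centers: Sequence[np.ndarray], r_w: float
) -> tuple[Arrangement, float]:
    """Left-turn-walk polygon set and its Gauss-Bonnet area a_gb (Å²)."""
    cons = probe_constraints(probe, neighbor_centers, r_w)
    arr = build_faces(cons, exhaustive=False)
    return arr, _polygon_area(arr, r_w)


def exhaustive_probe_polygons(
    probe: Probe, neighbor_centers: Sequence[np.ndarray], r_w: float
) -> tuple[Arrangement, float]:
    """Depth-first cycle enumeration plus interior-sample membership tests.

    Faces whose interior sample violates any constraint (an intersected
    inner region that survived stitching) are removed analytically.
    """
    cons = probe_constraints(probe, neighbor_centers, r_w)
    arr = build_faces(cons, exhaustive=True)
    kept = [
        f
        for f in arr.faces
        if all(c.signed_slack(f.sample) > -1e-9 for c in cons)
    ]
    arr.faces = kept
    return arr, _polygon_area(arr, r_w)


def estimate_probe_area(
    probe: Probe,
    neighbor_centers: Sequence[np.ndarray],
    r_w: float,
    level: int = DEFAULT_LEVEL,
) -> float:
    """Shrake-Rupley estimate of the clipped probe area (Å²)."""
    grid = unit_sphere_grid(level)
    cons = probe_constraints(probe, [], r_w)  # polygon sides only
    mask = np.ones(len(grid), dtype=bool)
    for c in cons:
        mask &= grid @ c.circle.axis >= 0.0
    for c_m in neighbor_centers:
        delta = np.asarray(c_m) - probe.center
        d = float(np.linalg.norm(delta))
        if d >= 2.0 * r_w or d < 1e-9:
            continue
        mask &= grid @ (delta / d) <= d / (2.0 * r_w)
    return r_w * r_w * float(grid_weights(level)[mask].sum())


def probe_area(
    probe: Probe,
    neighbor_centers: Sequence[np.ndarray],
    r_w: float,
    level: int = DEFAULT_LEVEL,
) -> Probe:
    """Fill ``a_gb``, ``a_es`` and the final ``a_p`` of one probe.

    Isolated probes keep their contact-polygon area.  Otherwise the greedy
    Gauss-Bonnet area is accepted only when it agrees with the grid estimate
    to better than ``GREEDY_CHECK_TOL``; on disagreement (or a failed greedy
    stitch) the exhaustive search is the result of record.
    """
    if len(neighbor_centers) == 0:
        probe.a_p = probe.a_tr
        return probe
    # a cap covering every contact point covers the whole (geodesically
    # convex) contact polygon: the probe is completely eaten
    dirs = np.array([_normalize(np.asarray(c) - probe.center) for c in probe.contacts])
    for c_m in neighbor_centers:
        delta = np.asarray(c_m) - probe.center
        d = float(np.linalg.norm(delta))
        if d >= 2.0 * r_w or d < 1e-9:
            continue
        if np.all(dirs @ (delta / d) >= d / (2.0 * r_w)):
            probe.a_p = 0.0
            return probe
    try:
        _arr, a_gb = greedy_probe_polygons(probe, neighbor_centers, r_w)
        probe.a_gb = a_gb
    except GeometryError:
        probe.a_gb = None
    probe.a_es = estimate_probe_area(probe, neighbor_centers, r_w, level)
    if probe.a_gb is not None and abs(probe.a_gb - probe.a_es) < GREEDY_CHECK_TOL:
        probe.a_p = probe.a_gb
    else:
        _arr, a_ex = exhaustive_probe_polygons(probe, neighbor_centers, r_w)
        probe.a_p = a_ex
        probe.used_exhaustive = True
    if probe.a_p < -1e-8:
        raise GeometryError(f"negative probe area {probe.a_p:.3e} Å²")
    if probe.a_p > probe.a_tr + 1e-6:
        raise GeometryError(
            f"probe area {probe.a_p:.6f} exceeds its isolated area "
            f"{probe.a_tr:.6f}"
        )
    probe.a_p = min(max(probe.a_p, 0.0), probe.a_tr)
    return probe


def resolve_probe_areas(
    probes: Sequence[Probe],
    r_w: float,
    level: int = DEFAULT_LEVEL,
) -> int:
    """Compute every probe's area in place; returns the number of probes
    that needed the exhaustive fallback."""
    lists = probe_neighbor_lists(probes, r_w)
    by_id = {p.id: p for p in probes}
    fallbacks = 0
    for p in probes:
        nbrs = [by_id[m].center for m in lists[p.id]]
        probe_area(p, nbrs, r_w, level)
        if p.used_exhaustive:
            fallbacks += 1
    return fallbacks
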