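"""Face extraction for intersections of circular half-surfaces on a sphere.

Both the per-atom accessible-surface problem and the per-probe polygon
problem reduce to the same question: given a set of circles on a unit
sphere, each with a prescribed side on which the region of interest lies,
find the connected faces of the set of points satisfying every side
constraint, together with their oriented boundary cycles, Euler
characteristics and solid angles.

For an atom the constraints are "outside every neighbor cap"; for a probe
they are "inside the contact triangle and outside every intersecting probe".

The construction follows the classic rolling-probe bookkeeping: split every
circle at its intersection points with the other circles, keep the arcs
whose midpoints satisfy all other constraints, orient them region-on-left,
and stitch cycles by always continuing along the accessible arc that makes
the sharpest left turn.  Cycles are then grouped into faces by a side-bit
signature: two cycles bound the same face exactly when every cycle of the
arrangement sees their sample points on the same side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Optional

import numpy as np

from .sphere_geom import (
    FOUR_PI,
    TWO_PI,
    Arc,
    Cycle,
    SmallCircle,
    SphericalRegionBoundary,
    _normalize,
    circle_circle_points,
    gauss_bonnet_area,
    turning_angle,
)


class GeometryError(RuntimeError):
    """Raised when the arrangement is internally inconsistent."""


@dataclass
class Constraint:
    """Region constraint: ``sign(x . axis - cos_alpha) == side``."""

    circle: SmallCircle
    side: int  # +1: region on the axis side of the circle
    tag: Any = None

    def signed_slack(self, x: np.ndarray) -> float:
        """Positive when ``x`` satisfies the constraint, negative inside the
        forbidden cap; magnitude is the margin in ``cos`` units."""
        return self.side * (float(x @ self.circle.axis) - self.circle.cos_alpha)


@dataclass
class Face:
    """One connected region of the arrangement."""

    cycles: list[Cycle]
    area_sr: float  # solid angle, steradians
    sample: np.ndarray  # a point in the open face
    bits: tuple[bool, ...] = ()

    @property
    def chi(self) -> int:
        return 2 - len(self.cycles)

    @property
    def kind(self) -> str:
        if not self.cycles:
            return "sphere"
        if len(self.cycles) == 1:
            return "cap" if self.cycles[0].is_full_circle else "polygon"
        return "band"


@dataclass
class Arrangement:
    constraints: list[Constraint]
    faces: list[Face]
    vertices: list[np.ndarray]  # unit vectors
    vertex_constraints: list[set[int]]  # constraint indices meeting there

    def classify_point(self, q: np.ndarray) -> Optional[int]:
        """Face index containing accessible point ``q`` (bit signature match)."""
        if not self.faces:
            return None
        all_cycles = [c for f in self.faces for c in f.cycles]
        if not all_cycles:
            return 0
        qbits = _point_bits(q, all_cycles)
        best, best_miss = None, None
        for idx, face in enumerate(self.faces):
            miss = sum(a != b for a, b in zip(qbits, face.bits))
            if best_miss is None or miss < best_miss:
                best, best_miss = idx, miss
        return best


# ---------------------------------------------------------------------------
# crossing tests

def _segment_crossings(q: np.ndarray, s: np.ndarray, arcs: list[Arc]) -> Optional[int]:
    """Number of transversal crossings of the minor geodesic q->s with arcs.

    Returns None when a crossing is too close to an arc endpoint or to a
    tangency to be trusted (caller retries along a different path).
    """
    g = np.cross(q, s)
    ng = float(np.linalg.norm(g))
    if ng < 1e-12:
        return 0  # q and s coincide (antipodal is not used by callers)
    g = g / ng
    qs = np.cross(q, s)
    count = 0
    for arc in arcs:
        n = arc.circle.axis
        c = arc.circle.cos_alpha
        gamma = float(n @ g)
        denom = 1.0 - gamma * gamma
        if denom < 1e-14:
            continue  # geodesic plane parallel to circle plane: no transversal hit
        a = c / denom
        b = -gamma * a
        t2 = (1.0 - a * a * denom) / denom
        if t2 < 1e-14:
            if t2 > -1e-14:
                return None  # grazing contact: ambiguous
            continue
        t = math.sqrt(t2)
        w = np.cross(n, g)
        base = a * n + b * g
        for sign in (1.0, -1.0):
            x = base + sign * t * w
            # on the geodesic segment between q and s?
            u1 = float(np.cross(q, x) @ qs)
            u2 = float(np.cross(x, s) @ qs)
            if u1 < 0.0 or u2 < 0.0:
                continue
            if min(u1, u2) < 1e-12:
                return None  # hits segment endpoint: ambiguous
            phi = arc.circle.azimuth(x)
            rel = ((phi - arc.phi_start) * arc.direction) % TWO_PI
            if arc.is_full_circle:
                inside = True
                near_end = False
            else:
                inside = rel <= arc.sweep
                near_end = min(rel, abs(arc.sweep - rel)) < 1e-9
            if near_end and not arc.is_full_circle:
                return None  # crossing at a vertex: ambiguous
            if inside:
                count += 1
    return count


def _same_side(q: np.ndarray, cycle: Cycle, sample: np.ndarray) -> bool:
    """True when ``q`` lies on the same side of ``cycle`` as ``sample``.

    Uses crossing parity of a geodesic path; retried through deterministic
    random waypoints when the direct path is ambiguous.
    """
    n = _segment_crossings(q, sample, cycle.arcs)
    if n is not None:
        return n % 2 == 0
    rng = np.random.default_rng(20240172)
    for _ in range(12):
        m = _normalize(rng.normal(size=3))
        n1 = _segment_crossings(q, m, cycle.arcs)
        n2 = _segment_crossings(m, sample, cycle.arcs)
        if n1 is not None and n2 is not None:
            return (n1 + n2) % 2 == 0
    raise GeometryError("could not resolve side of a boundary cycle")


def _cycle_sample(cycle: Cycle, offset: float = 1e-4) -> np.ndarray:
    """A point just inside the region bounded by ``cycle``."""
    arc = max(cycle.arcs, key=lambda a: a.sweep)
    x = arc.midpoint
    n = arc.circle.axis
    inward = arc.side * (n - float(n @ x) * x)
    norm = float(np.linalg.norm(inward))
    if norm < 1e-12:
        raise GeometryError("degenerate boundary arc")
    inward = inward / norm
    return _normalize(math.cos(offset) * x + math.sin(offset) * inward)


def _point_bits(q: np.ndarray, cycles: list[Cycle]) -> tuple[bool, ...]:
    return tuple(_same_side(q, c, _cycle_sample(c)) for c in cycles)


# ---------------------------------------------------------------------------
# main construction

def _stitch_greedy(directed: list[Arc]) -> list[Cycle]:
    """Partition directed arcs into cycles by sharpest-left-turn continuation."""
    out_arcs: dict[int, list[Arc]] = {}
    arc_index = {id(a): i for i, a in enumerate(directed)}
    for arc in directed:
        out_arcs.setdefault(arc.start_vertex, []).append(arc)
    unused = set(range(len(directed)))
    cycles: list[Cycle] = []
    while unused:
        start = directed[min(unused)]
        chain = [start]
        unused.discard(arc_index[id(start)])
        while True:
            cur = chain[-1]
            v = cur.end_vertex
            candidates = [a for a in out_arcs.get(v, []) if arc_index[id(a)] in unused]
            if v == start.start_vertex:
                candidates = candidates + [start]
            if not candidates:
                raise GeometryError("unclosed boundary cycle in arrangement")
            if len(candidates) == 1:
                nxt = candidates[0]
            else:
                t_in = cur.end_tangent
                vtx = cur.end_point
                nxt = max(
                    candidates,
                    key=lambda a: turning_angle(t_in, a.start_tangent, vtx),
                )
            if nxt is start:
                break
            chain.append(nxt)
            unused.discard(arc_index[id(nxt)])
        cycles.append(Cycle(arcs=chain))
    return cycles


def _stitch_exhaustive(directed: list[Arc]) -> list[Cycle]:
    """Partition directed arcs into cycles by depth-first search with
    backtracking over every possible continuation at each vertex."""
    out_arcs: dict[int, list[int]] = {}
    for idx, arc in enumerate(directed):
        out_arcs.setdefault(arc.start_vertex, []).append(idx)
    n = len(directed)
    used = [False] * n
    cycles_idx: list[list[int]] = []

    def search() -> bool:
        try:
            start = used.index(False)
        except ValueError:
            return True  # all arcs consumed
        chain = [start]
        used[start] = True

        def extend() -> bool:
            cur = directed[chain[-1]]
            v = cur.end_vertex
            if v == directed[chain[0]].start_vertex:
                cycles_idx.append(list(chain))
                if search():
                    return True
                cycles_idx.pop()
            for nxt in out_arcs.get(v, []):
                if used[nxt]:
                    continue
                used[nxt] = True
                chain.append(nxt)
                if extend():
                    return True
                chain.pop()
                used[nxt] = False
            return False

        ok = extend()
        if not ok:
            used[start] = False
        return ok

    if not search():
        raise GeometryError("no consistent cycle partition exists")
    return [Cycle(arcs=[directed[i] for i in chain]) for chain in cycles_idx]


def build_faces(
    constraints: list[Constraint], exhaustive: bool = False
) -> Arrangement:
    """Compute the faces of the region satisfying every constraint."""
    n_c = len(constraints)
    if n_c == 0:
        face = Face(cycles=[], area_sr=FOUR_PI, sample=np.array([0.0, 0.0, 1.0]))
        face.bits = ()
        return Arrangement([], [face], [], [])

    vertices: list[np.ndarray] = []
    vertex_constraints: list[set[int]] = []
    on_circle: dict[int, list[tuple[float, int]]] = {k: [] for k in range(n_c)}
    # spatial hash at the merge tolerance: points within 1e-7 share or
    # neighbor a 1e-6 cell, so only the 27 surrounding cells are probed
    cell_of: dict[tuple[int, int, int], list[int]] = {}
    scale = 1e6

    def add_vertex(p: np.ndarray, k: int, l: int) -> None:
        cx, cy, cz = (int(round(p[0] * scale)), int(round(p[1] * scale)),
                      int(round(p[2] * scale)))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for vid in cell_of.get((cx + dx, cy + dy, cz + dz), ()):
                        v = vertices[vid]
                        d2 = (
                            (v[0] - p[0]) ** 2
                            + (v[1] - p[1]) ** 2
                            + (v[2] - p[2]) ** 2
                        )
                        if d2 < 1e-14:
                            vertex_constraints[vid].update((k, l))
                            _register(vid, k, p)
                            _register(vid, l, p)
                            return
        vid = len(vertices)
        vertices.append(p)
        vertex_constraints.append({k, l})
        cell_of.setdefault((cx, cy, cz), []).append(vid)
        _register(vid, k, p)
        _register(vid, l, p)

    def _register(vid: int, k: int, p: np.ndarray) -> None:
        phi = constraints[k].circle.azimuth(p)
        for phi0, vid0 in on_circle[k]:
            if vid0 == vid:
                return
        on_circle[k].append((phi, vid))

    for k in range(n_c):
        for l in range(k + 1, n_c):
            pts = circle_circle_points(constraints[k].circle, constraints[l].circle)
            if len(pts) < 2:
                continue  # disjoint or tangent: treated as non-crossing
            for p in pts:
                add_vertex(p, k, l)

    # --- arcs --------------------------------------------------------------
    axes_mat = np.array([c.circle.axis for c in constraints])
    cosa_vec = np.array([c.circle.cos_alpha for c in constraints])
    side_vec = np.array([c.side for c in constraints], dtype=float)

    def satisfies_others(p: np.ndarray, k: int) -> bool:
        slack = side_vec * (axes_mat @ p - cosa_vec)
        slack[k] = np.inf
        return bool(slack.min() > 0.0)

    directed: list[Arc] = []
    free_cycles: list[Cycle] = []
    for k, cons in enumerate(constraints):
        circ = cons.circle
        pts = on_circle[k]
        if not pts:
            ok = satisfies_others(circ.point(0.0), k)
            if ok:
                free_cycles.append(
                    Cycle(
                        arcs=[
                            Arc(
                                circle=circ,
                                phi_start=0.0,
                                sweep=TWO_PI,
                                direction=cons.side,
                                side=cons.side,
                                tag=cons.tag,
                            )
                        ]
                    )
                )
            continue
        pts_sorted = sorted(pts)
        m = len(pts_sorted)
        for idx in range(m):
            phi_a, vid_a = pts_sorted[idx]
            phi_b, vid_b = pts_sorted[(idx + 1) % m]
            sweep = (phi_b - phi_a) % TWO_PI
            if sweep <= 1e-12:
                sweep = TWO_PI if m == 1 else sweep
                if sweep <= 1e-12:
                    continue
            mid = circ.point(phi_a + 0.5 * sweep)
            if not satisfies_others(mid, k):
                continue
            if cons.side == 1:
                arc = Arc(
                    circle=circ, phi_start=phi_a, sweep=sweep, direction=1,
                    side=1, tag=cons.tag, start_vertex=vid_a, end_vertex=vid_b,
                )
            else:
                arc = Arc(
                    circle=circ, phi_start=phi_b, sweep=sweep, direction=-1,
                    side=-1, tag=cons.tag, start_vertex=vid_b, end_vertex=vid_a,
                )
            directed.append(arc)

    # --- stitch directed arcs into closed cycles ---------------------------
    if exhaustive:
        cycles = _stitch_exhaustive(directed)
    else:
        cycles = _stitch_greedy(directed)
    cycles.extend(free_cycles)

    if not cycles:
        return Arrangement(constraints, [], vertices, vertex_constraints)

    # --- group cycles into faces by side-bit signature ---------------------
    def region_sample(cycle: Cycle) -> np.ndarray:
        s = None
        for offset in (1e-4, 1e-5, 1e-6, 1e-8):
            s = _cycle_sample(cycle, offset)
            if all(c.signed_slack(s) > 0.0 for c in constraints):
                return s
        return s  # thinnest faces: accept the smallest offset

    samples = [region_sample(c) for c in cycles]
    n_cy = len(cycles)
    bits = []
    for i in range(n_cy):
        row = []
        for j in range(n_cy):
            if i == j:
                row.append(True)
            else:
                row.append(_same_side(samples[i], cycles[j], samples[j]))
        bits.append(tuple(row))

    groups: dict[tuple, list[int]] = {}
    for i, b in enumerate(bits):
        groups.setdefault(b, []).append(i)

    faces: list[Face] = []
    for b, members in groups.items():
        face_cycles = [cycles[i] for i in members]
        u = gauss_bonnet_area(SphericalRegionBoundary(cycles=face_cycles))
        faces.append(
            Face(cycles=face_cycles, area_sr=u, sample=samples[members[0]], bits=b)
        )
    faces.sort(key=lambda f: f.area_sr)
    # re-derive bits in the sorted cycle order used by classify_point
    all_cycles = [c for f in faces for c in f.cycles]
    for f in faces:
        f.bits = _point_bits(f.sample, all_cycles)
    return Arrangement(constraints, faces, vertices, vertex_constraints)
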