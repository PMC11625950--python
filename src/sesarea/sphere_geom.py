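"""Exact spherical geometry kernel.

Everything here lives on a *unit* sphere: circles are stored by their unit
axis and ``cos(alpha)`` (``alpha`` = angular radius), boundary curves are
alternating sequences of vertices and small-circle arcs, and areas are solid
angles in steradians.  Scaling to a sphere of radius ``R`` multiplies areas
by ``R**2`` and is left to the callers.

Sign conventions
----------------
Boundary cycles are traversed so that the enclosed region lies on the LEFT
when the sphere is viewed from outside.  For an arc on a small circle with
unit axis ``n`` this means: traversal counter-clockwise about ``n``
(increasing azimuth) keeps the axis side of the circle on the left.  The
geodesic-curvature integral of an arc sweeping an azimuth ``theta`` is then
``dir * theta * cos(alpha)`` with ``dir = +1`` for counter-clockwise
traversal and ``-1`` for clockwise traversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

#: tolerance below which a circle-circle contact is treated as tangency
EPS_TAN = 1e-10
#: spatial tolerance for point coincidence (Å on molecular scales)
EPS_PT = 1e-6

TWO_PI = 2.0 * math.pi
FOUR_PI = 4.0 * math.pi


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def perpendicular_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair (e1, e2) with e1 x e2 = axis."""
    a = np.abs(axis)
    helper = np.zeros(3)
    helper[int(np.argmin(a))] = 1.0
    e1 = _normalize(np.cross(helper, axis))
    e2 = np.cross(axis, e1)
    return e1, e2


@dataclass
class SmallCircle:
    """A circle on the unit sphere: points x with ``x . axis = cos_alpha``."""

    axis: np.ndarray
    cos_alpha: float
    _frame: Optional[tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("circle axis must be a unit vector")
        if not (-1.0 < self.cos_alpha < 1.0):
            raise ValueError("angular radius must lie strictly in (0, pi)")

    @property
    def alpha(self) -> float:
        return math.acos(self.cos_alpha)

    @property
    def sin_alpha(self) -> float:
        return math.sqrt(max(0.0, 1.0 - self.cos_alpha * self.cos_alpha))

    @property
    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        if self._frame is None:
            self._frame = perpendicular_frame(self.axis)
        return self._frame

    def point(self, phi: float) -> np.ndarray:
        e1, e2 = self.frame
        return self.cos_alpha * self.axis + self.sin_alpha * (
            math.cos(phi) * e1 + math.sin(phi) * e2
        )

    def azimuth(self, x: np.ndarray) -> float:
        """Azimuth of a point (assumed on the circle) in [0, 2*pi)."""
        e1, e2 = self.frame
        phi = math.atan2(float(x @ e2), float(x @ e1))
        return phi % TWO_PI

    def tangent(self, phi: float, direction: int) -> np.ndarray:
        """Unit tangent of the circle at azimuth ``phi``.

        ``direction=+1`` for counter-clockwise traversal about the axis.
        """
        e1, e2 = self.frame
        t = -math.sin(phi) * e1 + math.cos(phi) * e2
        return direction * t


def intersection_circle(
    center_a: np.ndarray,
    radius_a: float,
    center_b: np.ndarray,
    radius_b: float,
) -> tuple[str, Optional[SmallCircle], float]:
    """Intersection of two spheres, expressed as a circle on sphere ``a``.

    Returns ``(kind, circle, h)`` where ``kind`` is one of

    - ``"circle"``   proper intersection; ``circle`` is on the *unit* sphere
      concentric with ``a`` (axis towards ``b``), ``h`` is the signed
      distance of the circle plane from ``a``'s center in Å;
    - ``"disjoint"`` the spheres do not overlap (tangency included);
    - ``"a_in_b"``   sphere ``a`` is engulfed by ``b``;
    - ``"b_in_a"``   sphere ``b`` lies inside ``a`` and removes nothing.
    """
    center_a = np.asarray(center_a, dtype=float)
    center_b = np.asarray(center_b, dtype=float)
    delta = center_b - center_a
    d = float(np.linalg.norm(delta))
    if d < EPS_PT:
        raise ValueError("coincident sphere centers are degenerate")
    if d >= radius_a + radius_b:
        return "disjoint", None, 0.0
    if d + radius_a <= radius_b:
        return "a_in_b", None, 0.0
    if d + radius_b <= radius_a:
        return "b_in_a", None, 0.0
    h = (d * d + radius_a * radius_a - radius_b * radius_b) / (2.0 * d)
    cos_alpha = h / radius_a
    if not (-1.0 < cos_alpha < 1.0):  # numerically grazing contact
        return "disjoint", None, 0.0
    return "circle", SmallCircle(axis=delta / d, cos_alpha=cos_alpha), h


def circle_circle_points(c1: SmallCircle, c2: SmallCircle) -> list[np.ndarray]:
    """Intersection points of two circles on the same unit sphere.

    Returns 0, 1 (tangency within tolerance) or 2 unit vectors.
    """
    n1, n2 = c1.axis, c2.axis
    gamma = float(n1 @ n2)
    denom = 1.0 - gamma * gamma
    if denom < 1e-18:
        same = (gamma > 0 and abs(c1.cos_alpha - c2.cos_alpha) < 1e-12) or (
            gamma < 0 and abs(c1.cos_alpha + c2.cos_alpha) < 1e-12
        )
        if same:
            raise ValueError("identical circles intersect everywhere")
        return []  # concentric distinct circles never cross
    a = (c1.cos_alpha - gamma * c2.cos_alpha) / denom
    b = (c2.cos_alpha - gamma * c1.cos_alpha) / denom
    w = np.cross(n1, n2)
    # |x|^2 = a^2 + b^2 + 2 a b gamma + t^2 |w|^2 = 1
    disc = 1.0 - (a * a + b * b + 2.0 * a * b * gamma)
    base = a * n1 + b * n2
    if disc < -EPS_TAN:
        return []
    if disc <= EPS_TAN:
        return [_normalize(base)]
    t = math.sqrt(disc)
    w_hat = w / math.sqrt(denom)
    return [_normalize(base + t * w_hat), _normalize(base - t * w_hat)]


def cap_area(alpha: float) -> float:
    """Solid angle of a spherical cap of angular radius ``alpha``."""
    if not (0.0 <= alpha <= math.pi):
        raise ValueError("cap angular radius must lie in [0, pi]")
    return TWO_PI * (1.0 - math.cos(alpha))


@dataclass
class Arc:
    """A directed small-circle arc of a boundary cycle.

    The arc runs from azimuth ``phi_start`` sweeping ``sweep > 0`` radians in
    the sense of ``direction`` (+1 counter-clockwise about the circle axis).
    ``side`` records on which side of the circle the enclosed region lies
    (+1 axis side); for a consistently oriented boundary ``side ==
    direction``.  ``tag`` carries the identity of the constraint that created
    the circle (e.g. a neighboring atom or probe index).
    """

    circle: SmallCircle
    phi_start: float
    sweep: float
    direction: int
    side: int
    tag: Any = None
    start_vertex: int = -1
    end_vertex: int = -1

    @property
    def phi_end(self) -> float:
        return (self.phi_start + self.direction * self.sweep) % TWO_PI

    @property
    def is_full_circle(self) -> bool:
        return self.start_vertex < 0

    def point_at(self, t: float) -> np.ndarray:
        return self.circle.point(self.phi_start + self.direction * self.sweep * t)

    @property
    def midpoint(self) -> np.ndarray:
        return self.point_at(0.5)

    @property
    def start_point(self) -> np.ndarray:
        return self.circle.point(self.phi_start)

    @property
    def end_point(self) -> np.ndarray:
        return self.circle.point(self.phi_end)

    @property
    def start_tangent(self) -> np.ndarray:
        return self.circle.tangent(self.phi_start, self.direction)

    @property
    def end_tangent(self) -> np.ndarray:
        return self.circle.tangent(self.phi_end, self.direction)

    def contains_azimuth(self, phi: float, tol: float = 1e-9) -> bool:
        rel = ((phi - self.phi_start) * self.direction) % TWO_PI
        return rel <= self.sweep + tol

    @property
    def length(self) -> float:
        return self.sweep * self.circle.sin_alpha


@dataclass
class Cycle:
    """A closed boundary cycle: either arcs joined at vertices or one full circle."""

    arcs: list[Arc]

    @property
    def is_full_circle(self) -> bool:
        return len(self.arcs) == 1 and self.arcs[0].is_full_circle

    @property
    def n_vertices(self) -> int:
        return 0 if self.is_full_circle else len(self.arcs)


def turning_angle(t_in: np.ndarray, t_out: np.ndarray, vertex: np.ndarray) -> float:
    """Signed exterior turning angle between two tangents at a vertex.

    Positive for a left turn when the sphere is viewed from outside.
    """
    s = float(np.cross(t_in, t_out) @ vertex)
    c = float(t_in @ t_out)
    return math.atan2(s, c)


@dataclass
class SphericalRegionBoundary:
    """Boundary of a region on the unit sphere with its Euler characteristic."""

    cycles: list[Cycle]

    @property
    def chi(self) -> int:
        # genus-0 regions only: a disk has one cycle, each hole removes one
        return 2 - len(self.cycles)


def gauss_bonnet_area(boundary: SphericalRegionBoundary) -> float:
    """Solid angle enclosed by a consistently oriented boundary.

    ``u = 2*pi*chi - sum(dir * theta * cos(alpha)) - sum(turning angles)``
    where the sums run over all arcs and vertices of all cycles.  A region
    with no boundary cycles is the full sphere (``chi = 2``, ``u = 4*pi``).
    """
    total = TWO_PI * boundary.chi
    for cycle in boundary.cycles:
        geod = 0.0
        turn = 0.0
        arcs = cycle.arcs
        for arc in arcs:
            geod += arc.direction * arc.sweep * arc.circle.cos_alpha
        if not cycle.is_full_circle:
            for k, arc in enumerate(arcs):
                prev = arcs[k - 1]
                if prev.end_vertex != arc.start_vertex:
                    raise ValueError("open boundary cycle passed to gauss_bonnet_area")
                turn += turning_angle(
                    prev.end_tangent, arc.start_tangent, arc.start_point
                )
        total -= geod + turn
    if total < -1e-8 or total > FOUR_PI + 1e-8:
        raise ValueError(
            f"Gauss-Bonnet area {total:.6g} outside [0, 4*pi]; "
            "boundary orientation is inconsistent"
        )
    return min(max(total, 0.0), FOUR_PI)


def spherical_triangle_excess(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Spherical excess (solid angle) of the minor triangle a, b, c.

    Uses l'Huilier's theorem on the three minor great-circle sides; returns 0
    for degenerate (collinear or coincident) vertices.
    """
    def side(u, v):
        return math.atan2(float(np.linalg.norm(np.cross(u, v))), float(u @ v))

    sa, sb, sc = side(b, c), side(c, a), side(a, b)
    s = 0.5 * (sa + sb + sc)
    prod = (
        math.tan(0.5 * s)
        * math.tan(0.5 * (s - sa))
        * math.tan(0.5 * (s - sb))
        * math.tan(0.5 * (s - sc))
    )
    if prod <= 0.0:
        return 0.0
    return 4.0 * math.atan(math.sqrt(prod))
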