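"""Per-atom solvent-accessible surface (SAS) region extraction.

Every atom is modeled as a sphere of radius ``r_a + r_w`` (its expanded, or
SAS, sphere).  The accessible part of that sphere is what remains after
removing the caps buried inside the expanded spheres of the neighboring
atoms.  The accessible part splits into connected *SAS regions*: spherical
caps (one free boundary circle), spherical polygons (one vertex/arc cycle)
and bands / polygons with holes (several boundary cycles, lower Euler
characteristic).  Regions are the atoms' currency for everything downstream:
their boundary vertices are the probe positions, their boundary arcs are the
tracks of the rolling probe around atom pairs, and surface components are
connected sets of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .arrangement import Arrangement, Constraint, GeometryError, build_faces
from .io_mol import AtomSet
from .sphere_geom import FOUR_PI, intersection_circle


@dataclass
class SASRegion:
    """One connected accessible region on one atom's expanded sphere."""

    id: int                    # global region index
    atom: int                  # 0-based atom index
    kind: str                  # sphere | cap | polygon | band
    chi: int                   # Euler-Poincare characteristic
    u_s: float                 # solid angle, steradians
    face_index: int            # index into the atom's arrangement faces
    component: Optional[int] = None

    def area(self, radius: float) -> float:
        """Area in Å² on a sphere of the given radius."""
        return self.u_s * radius * radius

    @property
    def n_cycles(self) -> int:
        return 2 - self.chi


@dataclass
class AtomSurface:
    """Arrangement and regions of a single atom, in local unit coordinates."""

    atom: int
    radius: float                      # expanded radius r_a + r_w
    neighbors: list[int]               # atoms contributing a circle
    arrangement: Optional[Arrangement]
    regions: list[SASRegion]
    buried: bool
    vertex_region: dict[int, int] = field(default_factory=dict)  # vid -> region id

    def vertex_world(self, vid: int, center: np.ndarray) -> np.ndarray:
        return center + self.radius * self.arrangement.vertices[vid]


@dataclass
class RegionSet:
    """All SAS regions of a molecule plus the per-atom surfaces and the map
    ``M_a`` from surface atoms to their region ids."""

    regions: list[SASRegion]
    surfaces: list[AtomSurface]
    atom_regions: dict[int, list[int]]  # M_a

    def __len__(self) -> int:
        return len(self.regions)


def neighbor_circles(
    i: int, atoms: AtomSet, tree: Optional[cKDTree] = None
) -> tuple[list[Constraint], bool, list[int]]:
    """Constraints (one per properly intersecting neighbor) for atom ``i``.

    Returns ``(constraints, engulfed, neighbor_indices)``; ``engulfed`` is
    True when a single neighbor swallows the whole expanded sphere.
    The constraint tag is the neighbor's atom index.
    """
    centers = atoms.centers
    R = atoms.expanded_radii
    if tree is None:
        tree = cKDTree(centers)
    candidates = tree.query_ball_point(centers[i], r=R[i] + R.max())
    constraints: list[Constraint] = []
    nbrs: list[int] = []
    for j in sorted(candidates):
        if j == i:
            continue
        kind, circle, _h = intersection_circle(centers[i], R[i], centers[j], R[j])
        if kind == "a_in_b":
            return [], True, []
        if kind != "circle":
            continue
        constraints.append(Constraint(circle=circle, side=-1, tag=j))
        nbrs.append(j)
    return constraints, False, nbrs


def extract_sas_regions(
    i: int, atoms: AtomSet, tree: Optional[cKDTree] = None
) -> AtomSurface:
    """All SAS regions of atom ``i`` (possibly none, for a buried atom)."""
    constraints, engulfed, nbrs = neighbor_circles(i, atoms, tree)
    radius = float(atoms.expanded_radii[i])
    if engulfed:
        return AtomSurface(i, radius, [], None, [], buried=True)
    try:
        arr = build_faces(constraints)
    except GeometryError as exc:
        raise GeometryError(f"atom {i + 1}: {exc}") from exc
    surface = AtomSurface(
        atom=i,
        radius=radius,
        neighbors=nbrs,
        arrangement=arr,
        regions=[],
        buried=not arr.faces,
    )
    for fidx, face in enumerate(arr.faces):
        region = SASRegion(
            id=-1,  # assigned globally by build_region_map
            atom=i,
            kind=face.kind,
            chi=face.chi,
            u_s=face.area_sr,
            face_index=fidx,
        )
        surface.regions.append(region)
    return surface


def build_region_map(atoms: AtomSet) -> RegionSet:
    """Extract regions for every atom; index them globally in atom order."""
    tree = cKDTree(atoms.centers)
    regions: list[SASRegion] = []
    surfaces: list[AtomSurface] = []
    atom_regions: dict[int, list[int]] = {}
    for i in range(len(atoms)):
        surface = extract_sas_regions(i, atoms, tree)
        for region in surface.regions:
            region.id = len(regions)
            regions.append(region)
        if surface.regions:
            atom_regions[i] = [r.id for r in surface.regions]
        _map_vertices_to_regions(surface)
        surfaces.append(surface)
    return RegionSet(regions=regions, surfaces=surfaces, atom_regions=atom_regions)


def _map_vertices_to_regions(surface: AtomSurface) -> None:
    """Record, for every arrangement vertex, the region whose boundary owns it."""
    if surface.arrangement is None:
        return
    for region in surface.regions:
        face = surface.arrangement.faces[region.face_index]
        for cycle in face.cycles:
            for arc in cycle.arcs:
                if arc.start_vertex >= 0:
                    surface.vertex_region[arc.start_vertex] = region.id
                    surface.vertex_region[arc.end_vertex] = region.id


def total_accessible_steradians(region_set: RegionSet, atom: int) -> float:
    return sum(r.u_s for r in region_set.regions if r.atom == atom)
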