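"""Surface component identification.

The surface of a molecule splits into connected components: the exterior
surface (e-surface) and the surfaces of internal cavities (i-surfaces),
each traceable by one rolling probe.  Components are found as connected
components of the region graph G_r whose nodes are all SAS regions and
whose edges join regions sharing a probe.  Free toroidal patches also
join their two regions — without this a probe-free molecule such as a
diatomic would split into two spurious components.

A single atom can contribute regions to several components (a shell atom
of a cavity has an outside face and an inside face); this is precisely why
components are identified on regions, not atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .arrangement import GeometryError
from .io_mol import AtomSet
from .probes_tori import Probe, ToroidalPatch
from .sas_regions import RegionSet


@dataclass
class SurfaceComponent:
    index: int
    regions: list[int]
    probes: list[int] = field(default_factory=list)
    tori: list[int] = field(default_factory=list)
    atoms: set[int] = field(default_factory=set)
    is_exterior: bool = False


def _exterior_region(atoms: AtomSet, region_set: RegionSet) -> int:
    """Region id containing the globally extreme +x surface point.

    That point (atom maximizing center_x + expanded radius, direction +x)
    cannot be covered by any neighbor, so its region is on the e-surface.
    """
    reach = atoms.centers[:, 0] + atoms.expanded_radii
    order = np.argsort(-reach)
    for i in map(int, order):
        surface = region_set.surfaces[i]
        if surface.arrangement is None or not surface.regions:
            continue
        fidx = surface.arrangement.classify_point(np.array([1.0, 0.0, 0.0]))
        if fidx is None:
            continue
        return surface.regions[fidx].id
    raise GeometryError("no surface regions to classify as exterior")


def identify_components(
    atoms: AtomSet,
    region_set: RegionSet,
    probes: list[Probe],
    tori: list[ToroidalPatch],
) -> list[SurfaceComponent]:
    """Connected components of G_r, largest first; index 0 is the e-surface."""
    if not region_set.regions:
        raise GeometryError("no SAS regions: cannot identify components")
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in region_set.regions)
    for probe in probes:
        regs = probe.regions
        for a in range(len(regs)):
            for b in range(a + 1, len(regs)):
                graph.add_edge(regs[a], regs[b])
    for patch in tori:
        graph.add_edge(patch.regions[0], patch.regions[1])

    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))

    exterior_idx = 0
    if len(comps) > 1 and len(comps[0]) == len(comps[1]):
        # size tie: exterior is the component holding the extreme +x region
        ext_region = _exterior_region(atoms, region_set)
        max_size = len(comps[0])
        for k, c in enumerate(comps):
            if len(c) < max_size:
                break
            if ext_region in c:
                exterior_idx = k
                break
    if exterior_idx != 0:
        comps[0], comps[exterior_idx] = comps[exterior_idx], comps[0]

    out = []
    for k, c in enumerate(comps):
        comp = SurfaceComponent(index=k, regions=c, is_exterior=(k == 0))
        comp.atoms = {region_set.regions[r].atom for r in c}
        out.append(comp)
    return out


def assign_components(
    components: list[SurfaceComponent],
    region_set: RegionSet,
    probes: list[Probe],
    tori: list[ToroidalPatch],
) -> None:
    """Stamp the component index onto every region, probe and patch."""
    comp_of_region: dict[int, int] = {}
    for comp in components:
        for r in comp.regions:
            region_set.regions[r].component = comp.index
            comp_of_region[r] = comp.index
    for probe in probes:
        idxs = {comp_of_region[r] for r in probe.regions}
        if len(idxs) != 1:
            raise GeometryError(
                f"probe {probe.id} spans components {sorted(idxs)}"
            )
        probe.component = idxs.pop()
        components[probe.component].probes.append(probe.id)
    for patch in tori:
        idxs = {comp_of_region[r] for r in patch.regions}
        if len(idxs) != 1:
            raise GeometryError(
                f"toroidal patch {patch.id} spans components {sorted(idxs)}"
            )
        patch.component = idxs.pop()
        components[patch.component].tori.append(patch.id)
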