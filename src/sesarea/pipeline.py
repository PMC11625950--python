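"""End-to-end surface computation and grid validation.

``compute`` runs the full analytic pipeline on an :class:`AtomSet`:
SAS region extraction -> probe and torus enumeration -> probe-probe
intersection resolution -> component identification -> area tables.

``validate_result`` re-measures every individual SAS region and every probe
polygon with the deterministic Shrake-Rupley grid and reports the absolute
deviations — the package's own accuracy audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import areas as areas_mod
from .components import SurfaceComponent, assign_components, identify_components
from .io_mol import AtomSet
from .ppi import estimate_probe_area, probe_neighbor_lists, resolve_probe_areas
from .probes_tori import Probe, ToroidalPatch, enumerate_probes, enumerate_tori
from .sas_regions import RegionSet, build_region_map
from .shrake_rupley import (
    DEFAULT_LEVEL,
    accessible_components,
    accessible_mask,
    grid_weights,
    unit_sphere_grid,
)

@dataclass
class SurfaceResult:
    """Everything the pipeline computed for one molecule."""

    atoms: AtomSet
    regions: RegionSet
    probes: list[Probe]
    tori: list[ToroidalPatch]
    components: list[SurfaceComponent]
    greedy_fallbacks: int = 0
    grid_level: int = DEFAULT_LEVEL
    _atom_tables: dict = field(default_factory=dict, repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.regions.regions)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_tori(self) -> int:
        return len(self.tori)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def atom_areas(self, component="exterior") -> pd.DataFrame:
        key = str(component)
        if key not in self._atom_tables:
            self._atom_tables[key] = areas_mod.atomic_areas(
                self.atoms, self.regions, self.probes, self.tori, component
            )
        return self._atom_tables[key]

    def component_areas(self) -> pd.DataFrame:
        return areas_mod.component_totals(
            self.atom_areas("all"), self.probes, self.tori
        )

    def component_report(self) -> list[dict]:
        return areas_mod.component_report(
            self.components, self.component_areas(), self.regions
        )


def compute(atoms: AtomSet, grid_level: int = DEFAULT_LEVEL) -> SurfaceResult:
    """Run the full analytic SES/SAS pipeline."""
    region_set = build_region_map(atoms)
    probes, vertex_map = enumerate_probes(atoms, region_set)
    tori = enumerate_tori(atoms, region_set, probes, vertex_map)
    fallbacks = resolve_probe_areas(probes, atoms.r_w, grid_level)
    components = identify_components(atoms, region_set, probes, tori)
    assign_components(components, region_set, probes, tori)
    return SurfaceResult(
        atoms=atoms,
        regions=region_set,
        probes=probes,
        tori=tori,
        components=components,
        greedy_fallbacks=fallbacks,
        grid_level=grid_level,
    )


# ---------------------------------------------------------------------------
# grid validation

def region_grid_estimates(
    result: SurfaceResult, level: Optional[int] = None
) -> dict[int, float]:
    """Shrake-Rupley estimate (Å²) of every individual SAS region.

    Accessible grid points are flood-filled into connected patches on the
    icosphere mesh; each patch is matched to the analytic region containing
    its best-cleared point, so multi-region atoms are split correctly.
    """
    level = level if level is not None else result.grid_level
    grid = unit_sphere_grid(level)
    weights = grid_weights(level)
    atoms = result.atoms
    centers = atoms.centers
    R = atoms.expanded_radii
    estimates: dict[int, float] = {}
    for surface in result.regions.surfaces:
        if not surface.regions:
            continue
        i = surface.atom
        excluders = [(centers[j], float(R[j])) for j in surface.neighbors]
        mask = accessible_mask(centers[i], float(R[i]), excluders, grid)
        r2 = float(R[i]) ** 2
        if len(surface.regions) == 1:
            estimates[surface.regions[0].id] = r2 * float(weights[mask].sum())
            continue
        n_comp, labels = accessible_components(mask, level)
        totals = {r.id: 0.0 for r in surface.regions}
        if n_comp == 0:
            estimates.update({rid: 0.0 for rid in totals})
            continue
        # clearance of each accessible point from every excluder circle
        arr = surface.arrangement
        axes = np.array([c.circle.axis for c in arr.constraints])
        cosa = np.array([c.circle.cos_alpha for c in arr.constraints])
        slack = cosa[None, :] - grid @ axes.T  # >0 outside the cap
        for lab in range(n_comp):
            pts = np.flatnonzero(labels == lab)
            rep = pts[int(np.argmax(slack[pts].min(axis=1)))]
            fidx = arr.classify_point(grid[rep])
            rid = surface.regions[fidx].id
            totals[rid] += float(weights[pts].sum())
        for rid, w_sum in totals.items():
            estimates[rid] = r2 * w_sum
    return estimates


def cluster_ensemble_deviation(
    seeds,
    box: float = 12.0,
    n_range: tuple[int, int] = (20, 60),
    level: int = DEFAULT_LEVEL,
) -> tuple[float, int]:
    """Worst |analytic - grid| deviation over an ensemble of random clusters.

    For each seed a cluster of ``n`` atoms (n drawn uniformly from
    ``n_range`` with the same seed) is generated in a cubic box, the full
    pipeline is run, and every individual SAS region and probe area is
    compared against the Shrake-Rupley grid estimate.  Returns
    ``(max_abs_deviation, number_of_areas_compared)``.
    """
    from .fixtures import random_cluster

    worst = 0.0
    n_compared = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        atoms = random_cluster(n=n, box=box, seed=seed)
        result = compute(atoms, grid_level=level)
        dev = validate_result(result, level=level)
        if len(dev):
            worst = max(worst, float(dev["abs_diff"].max()))
            n_compared += len(dev)
    return worst, n_compared


def validate_result(
    result: SurfaceResult, level: Optional[int] = None
) -> pd.DataFrame:
    """Deviation table |analytic - grid estimate| for regions and probes."""
    level = level if level is not None else result.grid_level
    atoms = result.atoms
    rows = []
    region_est = region_grid_estimates(result, level)
    for region in result.regions.regions:
        radius = float(atoms.expanded_radii[region.atom])
        analytic = region.u_s * radius * radius
        est = region_est[region.id]
        rows.append(
            {
                "kind": "region",
                "id": region.id,
                "atom": region.atom + 1,
                "analytic": analytic,
                "estimate": est,
                "abs_diff": abs(analytic - est),
            }
        )
    lists = probe_neighbor_lists(result.probes, atoms.r_w)
    by_id = {p.id: p for p in result.probes}
    for probe in result.probes:
        nbrs = [by_id[m].center for m in lists[probe.id]]
        est = (
            probe.a_es
            if probe.a_es is not None
            else estimate_probe_area(probe, nbrs, atoms.r_w, level)
        )
        rows.append(
            {
                "kind": "probe",
                "id": probe.id,
                "atom": probe.atoms[0] + 1,
                "analytic": probe.a_p,
                "estimate": est,
                "abs_diff": abs(probe.a_p - est),
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["kind", "id", "atom", "analytic", "estimate", "abs_diff"]
    )
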