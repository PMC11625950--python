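"""Atomic and molecular area aggregation.

Per surface atom ``i`` the solvent-excluded surface (SES) area is

    a(i) = a_s(i) + a_c(i),      a_c(i) = a_t(i) + a_p(i)

where ``a_s`` is the SAS (contact) area, ``a_t(i)`` collects half of every
toroidal patch the atom borders and ``a_p(i)`` one third of every probe it
defines.  The SAS solid angle ``u_s`` is reported in both conventions:
scaled by ``r_a**2`` (the vdW convention used in SES totals) and by
``(r_a + r_w)**2`` (the conventional SASA).  Component totals ``A_s`` and
``A_c`` are plain sums over the atoms of one surface component.
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

import pandas as pd

from .components import SurfaceComponent
from .io_mol import AtomSet
from .probes_tori import Probe, ToroidalPatch
from .sas_regions import RegionSet

ComponentFilter = Union[str, int]  # "exterior", "all", or a component index


def _wanted(component: ComponentFilter, idx: int) -> bool:
    if component == "all":
        return True
    if component == "exterior":
        return idx == 0
    return idx == int(component)


def atomic_areas(
    atoms: AtomSet,
    region_set: RegionSet,
    probes: Iterable[Probe],
    tori: Iterable[ToroidalPatch],
    component: ComponentFilter = "exterior",
) -> pd.DataFrame:
    """Per-atom area table; one row per (atom, component) pair.

    Columns: atom_index (1-based), element, component, a_s_vdw,
    a_s_expanded, a_t, a_p, a_c, a — all Å², with ``a = a_s_vdw + a_c``.
    """
    r = atoms.radii
    r_w = atoms.r_w
    rows: dict[tuple[int, int], dict] = {}

    def row(atom: int, comp: int) -> dict:
        key = (atom, comp)
        if key not in rows:
            rows[key] = {
                "atom_index": atom + 1,
                "element": atoms.atoms[atom].element or "",
                "component": comp,
                "u_s": 0.0,
                "a_t": 0.0,
                "a_p": 0.0,
            }
        return rows[key]

    for region in region_set.regions:
        if region.component is None:
            raise ValueError(f"region {region.id} has no component assigned")
        if not _wanted(component, region.component):
            continue
        row(region.atom, region.component)["u_s"] += region.u_s

    for patch in tori:
        if not _wanted(component, patch.component):
            continue
        for atom in patch.atoms:
            row(atom, patch.component)["a_t"] += 0.5 * patch.a_t

    for probe in probes:
        if not _wanted(component, probe.component):
            continue
        share = (probe.a_p or 0.0) / len(probe.atoms)
        for atom in probe.atoms:
            row(atom, probe.component)["a_p"] += share

    records = []
    for (atom, comp), data in sorted(rows.items()):
        u_s = data.pop("u_s")
        a_s_vdw = u_s * r[atom] ** 2
        a_s_exp = u_s * (r[atom] + r_w) ** 2
        a_c = data["a_t"] + data["a_p"]
        records.append(
            {
                **data,
                "a_s_vdw": a_s_vdw,
                "a_s_expanded": a_s_exp,
                "a_c": a_c,
                "a": a_s_vdw + a_c,
            }
        )
    columns = [
        "atom_index", "element", "component",
        "a_s_vdw", "a_s_expanded", "a_t", "a_p", "a_c", "a",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def component_totals(
    atom_table: pd.DataFrame,
    probes: Iterable[Probe],
    tori: Iterable[ToroidalPatch],
    conservation_tol: float = 1e-6,
) -> pd.DataFrame:
    """Component totals with conservation checks.

    The per-atom probe thirds and toroidal halves must add back to the sums
    over probes and patches; a violation indicates an aggregation bug and is
    fatal.
    """
    totals = (
        atom_table.groupby("component")
        .agg(
            N_s=("atom_index", "count"),
            A_s_vdw=("a_s_vdw", "sum"),
            A_s_expanded=("a_s_expanded", "sum"),
            A_t=("a_t", "sum"),
            A_p=("a_p", "sum"),
            A_c=("a_c", "sum"),
            A=("a", "sum"),
        )
        .reset_index()
    )
    present = set(totals["component"])
    probe_sum = {c: 0.0 for c in present}
    tori_sum = {c: 0.0 for c in present}
    for probe in probes:
        if probe.component in probe_sum:
            probe_sum[probe.component] += probe.a_p or 0.0
    for patch in tori:
        if patch.component in tori_sum:
            tori_sum[patch.component] += patch.a_t
    for _, rec in totals.iterrows():
        c = rec["component"]
        if abs(rec["A_p"] - probe_sum[c]) > conservation_tol:
            raise ValueError(
                f"probe-area conservation violated in component {c}: "
                f"{rec['A_p']:.8f} vs {probe_sum[c]:.8f}"
            )
        if abs(rec["A_t"] - tori_sum[c]) > conservation_tol:
            raise ValueError(
                f"toroidal-area conservation violated in component {c}: "
                f"{rec['A_t']:.8f} vs {tori_sum[c]:.8f}"
            )
    return totals


def diff_area_tables(
    ours: pd.DataFrame,
    theirs: pd.DataFrame,
    column: str = "a_s_expanded",
    their_column: Optional[str] = None,
) -> tuple[pd.DataFrame, dict]:
    """Atom-level and molecule-level differences between two area tables.

    Both tables must have an ``atom_index`` column.  Deltas are computed on
    the intersection of atom sets (ours minus theirs); atoms present in only
    one table are excluded from the sums but counted in ``d_N``.  Summary
    percentages follow the convention dN_p = 100*d_N/N_ours and
    dA_p = 100*|dA|/A_ours.
    """
    their_column = their_column or column
    a = ours.set_index("atom_index")[column]
    b = theirs.set_index("atom_index")[their_column]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no atoms in common between the two tables")
    da = (a.loc[common] - b.loc[common]).rename("delta")
    per_atom = da.reset_index()
    d_n = len(a) - len(b)
    total = float(a.sum())
    summary = {
        "n_ours": len(a),
        "n_theirs": len(b),
        "n_common": len(common),
        "d_N": d_n,
        "dA": float(da.sum()),
        "sum_abs_da": float(da.abs().sum()),
        "max_abs_da": float(da.abs().max()),
        "dN_p": 100.0 * d_n / len(a) if len(a) else float("nan"),
        "dA_p": 100.0 * abs(float(da.sum())) / total if total else float("nan"),
        "only_ours": sorted(a.index.difference(b.index)),
        "only_theirs": sorted(b.index.difference(a.index)),
    }
    return per_atom, summary


def component_report(
    components: list[SurfaceComponent],
    totals: pd.DataFrame,
    region_set: RegionSet,
) -> list[dict]:
    """JSON-serializable per-component summary."""
    by_comp = totals.set_index("component")
    report = []
    for comp in components:
        rec = {
            "component": comp.index,
            "is_exterior": comp.is_exterior,
            "n_atoms": len(comp.atoms),
            "n_regions": len(comp.regions),
            "n_probes": len(comp.probes),
            "n_tori": len(comp.tori),
        }
        if comp.index in by_comp.index:
            row = by_comp.loc[comp.index]
            rec.update(
                A_s_vdw=float(row["A_s_vdw"]),
                A_s_expanded=float(row["A_s_expanded"]),
                A_c=float(row["A_c"]),
                A=float(row["A"]),
            )
        report.append(rec)
    return report
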