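"""Molecule input/output: xyzr and PDB readers, radius tables, area tables.

The interchange format is the msms-style ``xyzr`` file: one whitespace
separated ``x y z r`` record per atom (extra columns ignored).  A small PDB
reader (via gemmi) is provided for convenience; radii are then assigned from
an element -> radius table.  The default table is the van der Waals set
C 1.70, N 1.55, O 1.52, S 1.75, H 1.09 Å, used with a water probe of
radius 1.4 Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: van der Waals radii (Å) for the supported elements
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.75,
    "H": 1.09,
}

#: water probe radius (Å)
DEFAULT_PROBE_RADIUS = 1.4


class InputError(ValueError):
    """Malformed or degenerate molecular input."""


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based internal index, optional element symbol, center (Å),
    van der Waals radius (Å).  External (file-order) indices are 1-based."""

    index: int
    element: Optional[str]
    center: np.ndarray
    radius: float

    def __post_init__(self):
        if not self.radius > 0.0:
            raise InputError(f"atom {self.index + 1}: radius must be positive")
        if not np.all(np.isfinite(self.center)):
            raise InputError(f"atom {self.index + 1}: non-finite coordinates")


@dataclass
class AtomSet:
    """An ordered molecule plus the probe radius it is analyzed with."""

    atoms: list[Atom]
    r_w: float = DEFAULT_PROBE_RADIUS
    _centers: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if not self.atoms:
            raise InputError("empty atom set")
        if not self.r_w > 0.0:
            raise InputError("probe radius must be positive")
        c = self.centers
        # duplicate coordinates make every downstream circle degenerate
        if len(self.atoms) > 1:
            from scipy.spatial import cKDTree

            pairs = cKDTree(c).query_pairs(1e-6)
            if pairs:
                i, j = sorted(next(iter(pairs)))
                raise InputError(
                    f"atoms {i + 1} and {j + 1} coincide within 1e-6 Å"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def centers(self) -> np.ndarray:
        if self._centers is None:
            self._centers = np.array([a.center for a in self.atoms], dtype=float)
        return self._centers

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def expanded_radii(self) -> np.ndarray:
        """Solvent-expanded radii r_a + r_w (the SAS sphere radii)."""
        return self.radii + self.r_w

    @property
    def elements(self) -> list[Optional[str]]:
        return [a.element for a in self.atoms]


def _read_xyzr(path: Path, r_w: float) -> AtomSet:
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected at least 4 fields")
            try:
                x, y, z, r = (float(v) for v in parts[:4])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed record") from exc
            atoms.append(
                Atom(index=len(atoms), element=None,
                     center=np.array([x, y, z]), radius=r)
            )
    return AtomSet(atoms=atoms, r_w=r_w)


def _read_pdb(path: Path, radii: dict[str, float], r_w: float) -> AtomSet:
    import gemmi

    structure = gemmi.read_structure(str(path))
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    element = atom.element.name.upper()
                    if element not in radii:
                        raise InputError(
                            f"element {element!r} (atom {atom.name} in "
                            f"{residue.name}) not in the radius table"
                        )
                    atoms.append(
                        Atom(
                            index=len(atoms),
                            element=element,
                            center=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            radius=radii[element],
                        )
                    )
        break  # first model only
    return AtomSet(atoms=atoms, r_w=r_w)


def read_structure(
    path: str | Path,
    format: Optional[str] = None,
    radii: Optional[dict[str, float]] = None,
    r_w: float = DEFAULT_PROBE_RADIUS,
) -> AtomSet:
    """Read a molecule from an xyzr or PDB file.

    ``format`` defaults to the file suffix.  xyzr records carry their own
    radii; PDB atoms are assigned radii from ``radii`` (default: the built-in
    van der Waals table) and unknown elements are a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyzr"
    if format == "xyzr":
        return _read_xyzr(path, r_w)
    if format == "pdb":
        table = dict(DEFAULT_RADII if radii is None else radii)
        for el, r in table.items():
            if not r > 0:
                raise InputError(f"radius table entry {el} must be positive")
        return _read_pdb(path, table, r_w)
    raise InputError(f"unknown format {format!r}")


def write_xyzr(atoms: AtomSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in atoms.atoms:
            x, y, z = a.center
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {a.radius:.6f}\n")


def write_area_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-atom area table as TSV (areas to 4 decimals)."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def write_component_report(report: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
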