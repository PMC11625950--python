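# sesarea

Analytic computation of solvent-excluded surface (SES) and
solvent-accessible surface (SAS) areas for molecules, with exhaustive
probe–probe intersection resolution and internal-cavity detection.

## Who this is for

Structural bioinformaticians and molecular modellers who need *exact*
per-atom surface areas — not grid or Monte-Carlo estimates — and who need
the exterior surface separated from the surfaces of internal cavities.
Surface areas drive solvation terms, interface analyses and cavity
characterization; at the individual-atom level the dominant source of
error in analytic SES programs is the treatment of probe–probe
intersections, which this package resolves exhaustively and audits
numerically.

## The model

A molecule is a set of atoms with van der Waals radii `r_a` (defaults:
C 1.70, N 1.55, O 1.52, S 1.75, H 1.09 Å), probed by a solvent sphere of
radius `r_w` (1.4 Å for water). Three kinds of patches make up the SES:

- **SAS (contact) regions** — the accessible parts of each atom's expanded
  sphere of radius `r_a + r_w`: the sphere minus the caps buried inside
  neighboring expanded spheres. A region is a cap, a spherical polygon, or
  a band / polygon with holes, distinguished by its Euler–Poincaré
  characteristic χ. Its solid angle `u_s` is computed with the
  Gauss–Bonnet theorem, `u = 2πχ − Σ(±θ·cos α) − Σ τ`, over its boundary
  arcs and vertex turning angles.
- **Fixed probes** — probe spheres tangent to three atoms at once; their
  centers are exactly the boundary vertices of the SAS regions. The probe
  contributes a concave spherical triangle clipped by every intersecting
  probe (centers closer than `2 r_w`).
- **Toroidal patches** — saddles swept by the probe arc rolling around an
  atom pair, bounded by two probes (or a full torus when free); spindle
  tori (`r_c < r_w`) are truncated at the self-intersection cusp.

Per atom `i`:

    a(i) = a_s(i) + a_c(i),   a_c(i) = a_t(i) + a_p(i)
    a_t(i) = ½ Σ_j a_t(i,j),  a_p(i) = ⅓ Σ_{j,k} a_p(i,j,k)
    a_s(i) = u_s(i)·r_i²  (vdW convention)   or   u_s(i)·(r_i+r_w)²  (SASA)

Surface components (exterior surface vs cavity surfaces) are the connected
components of the graph whose nodes are SAS regions and whose edges join
regions sharing a probe (plus free-torus links); the largest is the
e-surface. Probe areas are self-checking: a greedy Gauss–Bonnet result is
accepted only when it agrees with a 40,962-point numerical estimate to
10⁻² Å², otherwise an exhaustive cycle search with analytic removal of all
intersected inner regions is the result of record.

## Worked example

```python
from sesarea import compute, diatomic

atoms, _ = diatomic(d=1.5)      # two carbons 1.5 Å apart
result = compute(atoms)
print(result.atom_areas("exterior"))
```

prints

```
 atom_index element  component   a_s_vdw  a_s_expanded      a_t  a_p      a_c         a
          1       C          0 22.551568     74.989817 3.486060  0.0 3.486060 26.037628
          2       C          0 22.551568     74.989817 3.486060  0.0 3.486060 26.037628
```

`a_s_expanded` is each atom's SASA and matches the closed form
`2πR(R + d/2) = 74.989817 Å²` with `R = 3.10 Å` exactly; `a_t` is each
atom's half of the free toroidal saddle around the bond; `a` is the SES
area (vdW-scaled contact patch plus concave area). The same pipeline on a
hollow shell of atoms reports two surface components — exterior and
cavity — with separate totals (see `examples/cavity_detection.py`).

A command-line interface mirrors the library:

```
sesarea fixtures diatomic --out dia.xyzr
sesarea compute --in dia.xyzr --out-table areas.tsv --out-report comps.json
sesarea validate --in dia.xyzr
```

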