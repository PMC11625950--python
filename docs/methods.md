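# Methods

This note documents the geometric model, the algorithms, the numerical
conventions, and the limits of what the test suite demonstrates.

## Surface model

Atoms are hard spheres with van der Waals radii; the solvent is a probe
sphere of radius `r_w` (default 1.4 Å, water). Two closely related
surfaces are computed:

- the **solvent-accessible surface** (SAS), traced by the probe *center*:
  per atom it lives on the expanded sphere of radius `R = r_a + r_w`;
- the **solvent-excluded surface** (SES), the envelope of the probe's
  inward face: convex contact patches (the SAS regions re-scaled to the
  vdW sphere), concave probe patches, and toroidal saddles.

The default radius table is C 1.70, N 1.55, O 1.52, S 1.75, H 1.09 Å.
Inputs are taken as given (protonation and structure cleaning are
preprocessing, out of scope); xyzr records carry their own radii and
override the table.

## SAS region extraction

For atom `i`, every neighbor `j` whose expanded sphere properly intersects
`i`'s contributes an *intersection circle* on `i`'s expanded sphere
(plane offset `h = (d² + R_i² − R_j²)/2d`). The accessible set is the
sphere minus the union of the neighbor caps. Its connected faces — the SAS
regions — are extracted by an arrangement computation shared with the
probe-clipping step:

1. all circle–circle intersection points are computed exactly (two-plane /
   sphere solve) and deduplicated within `1e-7` on the unit sphere;
2. each circle is split at its points; arcs whose midpoints violate any
   other constraint are discarded; circles with no surviving points and an
   accessible sample point become free (full-circle) boundaries;
3. arcs are oriented region-on-left (for a buried cap this is clockwise
   about the cap axis) and stitched into closed cycles; at a generic vertex
   the continuation is unique, at degenerate multi-circle vertices the
   sharpest left turn is taken;
4. cycles are grouped into faces by a *side-bit signature*: for every
   cycle, every other cycle's interior sample is classified by crossing
   parity of a geodesic path; cycles bounding the same face see all
   samples on the same sides. For the generically disjoint boundary
   cycles of a sphere arrangement this signature identifies faces exactly;
5. each face's solid angle follows from Gauss–Bonnet,
   `u = 2πχ − Σ dir·θ·cos α − Σ τ`, with `χ = 2 − (number of cycles)`,
   `θ` the arc sweep, `α` its angular radius, and `τ` the signed turning
   angle between arc tangents at each vertex. Results outside
   `[−1e−8, 4π + 1e−8]` abort the run (orientation inconsistency).

An atom engulfed by a single neighbor, or whose circles are all buried,
has no regions. There is no cap on the number of regions per atom.

## Probes and toroidal patches

Every boundary vertex of the arrangement, scaled back to world
coordinates, is at distance `r_t + r_w` from exactly three atoms — a fixed
probe position. Probes are enumerated by clustering these vertices across
atoms (union-find within 1e-6 Å; a quadruple-contact coincidence merges
into one probe carrying all incident regions). This construction is
verified against brute-force trilateration over all atom triples with a
strict-interiority blocking filter (tangent contacts are not collisions).

Each accessible arc of an atom-pair circle is the track of the probe
center around that pair: one toroidal patch per arc, bounded by the
endpoint probes, or a full torus (`φ = 2π`) for a free circle. With the
contact angles `θ` measured from the plane of the probe-center circle, a
patch's area is the surface-of-revolution integral

    a_t = φ · [ r_c·r_w·θ − r_w²·sin θ ]  evaluated over [θ_i, θ_j],

where `r_c` is the probe-center circle radius; for spindle tori
(`r_c < r_w`) the self-intersecting piece `|θ| < arccos(r_c/r_w)` is
removed. The closed form is validated against 1-D quadrature in the test
suite. Patch areas are split half/half between the two atoms regardless
of radius asymmetry; probe areas one-third each.

## Probe–probe intersections

Two probes intersect iff their centers are closer than `2 r_w` (strict).
Intersections are resolved against **all** probes of the molecule,
including probes of other surface components — a cavity probe clips an
exterior probe all the same. On the probe sphere the constraints are the
three great-circle sides of the contact triangle (ordered
counter-clockwise about the mean contact direction) plus one cap per
intersecting probe (`cos α = d/2r_w`). The probe-area algorithm:

- isolated probe: `a_p = a_tr`, the spherical-polygon excess of the
  contact directions times `r_w²`;
- otherwise the greedy (left-turn) arrangement gives `a_gb`; a
  deterministic Shrake–Rupley estimate `a_es` on the same constraints
  guards it; `a_gb` is accepted iff `|a_gb − a_es| < 10⁻²` Å²;
- on disagreement or a failed stitch, an exhaustive depth-first search
  over every cycle partition of the boundary graph recomputes the polygon
  set, and every face is verified by interior-sample membership tests
  against all constraints (intersected inner regions removed analytically).

Negative probe areas and areas exceeding `a_tr` abort the run; a cap
containing all contact points covers the whole (geodesically convex)
triangle and short-circuits to `a_p = 0`. Two performance filters drop
constraints that provably cannot change the result: caps entirely outside
the triangle, and caps engulfed by an already-kept cap.

## Surface components

The region graph `G_r` has all SAS regions as nodes; each probe connects
its three regions pairwise, and each free toroidal patch connects its two
regions (without the free-torus edges a probe-free diatomic would split
into two spurious components — a deliberate extension for degenerate
molecules). Components of the undirected graph (identical to
strongly-connected components in this symmetric setting) are sorted by
region count; the largest is flagged exterior. Ties are broken physically:
the region containing the globally extreme `+x` surface point (which no
neighbor can cover) must be exterior. One atom's regions may land in
different components — shell atoms of a cavity face both surfaces — and
the cage fixture exhibits this.

## Numerical estimator

The Shrake–Rupley grid is a subdivided icosahedron projected to the unit
sphere (`10·4^level + 2` points; level 6 = 40,962, the default
everywhere). Two engineering choices matter:

- **vertex weights**: projected icosphere vertices are only nearly
  uniform; unweighted counting carries a systematic density bias of a few
  tenths of a percent that does not shrink with subdivision. Each vertex is
  therefore weighted by one third of its incident spherical triangle
  areas (weights sum to 4π exactly), which removes the bias;
- **fixed generic rotation** of the base icosahedron, so that the grid's
  symmetry planes never coincide with coordinate axes and axis-aligned
  fixtures do not place whole point rings exactly on region boundaries.

Tangent excluders do not flip points (`1e-6` Å slack, matching the
analytic side). Per-region estimates flood-fill accessible points over the
icosphere mesh and assign each connected patch to the analytic face
containing its best-cleared point.

## Tolerances

- point coincidence (vertex merging, probe clustering): `1e-6` Å;
- circle–circle tangency: treated as non-crossing below `1e-10` on the
  intersection discriminant;
- accessibility of arc midpoints: strict sign tests in double precision;
- greedy/estimate gate: `1e-2` Å²; conservation checks `1e-6` Å²;
- geodesic side tests retry through deterministic random waypoints when a
  crossing falls within `1e-9` of an arc endpoint.

All arithmetic is double precision; no exact/rational fallback and no
general-position perturbation is attempted.

## Synthetic data

The fixture generators cover every motif the pipeline must handle:
isolated atom (full-sphere region), diatomic (caps + free torus), an
equilateral triple (mirror probe pair; each pair circle keeps a single
accessible arc, so three saddle patches), a tetrahedron (probe blocking by
the fourth atom), a spindle pair (`d = 5.8` Å C–C, `r_c ≈ 1.10 < r_w`), a
cage (30 shell atoms at 4.5 Å — sealed cavity with interior probes), and
seeded random clusters. Clusters draw uniform positions in a cubic box
with a 1.0 Å minimum spacing — close enough to bury and even engulf
hydrogens, which exercises the buried-atom paths — and element frequencies
roughly matching protonated proteins (H 50%, C 32%, O 9%, N 8%, S 1%).
The ensemble used by `scripts/acceptance.py` (50 clusters, 20–60 atoms,
12 Å box) keeps single-CPU runtime around a minute.

What the synthetic conditions do *not* emulate: covalent bonding geometry,
realistic secondary structure, and crystallographic pathologies (alternate
locations beyond the A-filter, occupancies). Passing tests therefore
demonstrate geometric and topological correctness of the surface
machinery, not force-field realism; on real structures the same code paths
run, but input cleaning is the user's responsibility.

## Known limitations

- Region faces are grouped by pairwise side signatures, which is exact for
  disjoint boundary cycles (the generic case) but could misgroup contrived
  arrangements in which distinct faces share identical signatures; the
  grid audit would flag such a case.
- Near-tangent circles (separation below the tangency threshold) are
  treated as non-crossing; sliver regions thinner than ~1e-8 radians may
  be missed.
- The exterior flag follows the largest-component rule; for pathological
  inputs where a cavity has more regions than the exterior surface the
  flag would be wrong (the extreme-point test is applied only to break
  exact ties).
- Disconnected molecules are reported as a single result with one
  component per body, only the largest flagged exterior.
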