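"""Detect an internal cavity and split areas by surface component.

A shell of 30 carbon atoms on a 4.5 Å sphere encloses a void large enough
for a 1.4 Å probe but sealed against escape.  The surface therefore splits
into two components: the exterior surface (largest, index 0) and the
cavity's interior surface.  Every shell atom contributes one region to
each — the reason components are identified on regions, not atoms.
"""

import json

from sesarea import cage, compute

atoms, _ = cage(radius=4.5, n_shell=30, seed=7)
result = compute(atoms)

print(json.dumps(result.component_report(), indent=2))

exterior = result.atom_areas("exterior")
cavity = result.atom_areas(1)
print(f"\nexterior SASA : {exterior['a_s_expanded'].sum():9.3f} Å²")
print(f"cavity   SASA : {cavity['a_s_expanded'].sum():9.3f} Å²")
print("The cavity's probes and saddles are real SES elements: a water "
      "molecule trapped inside could touch them, but none of its probes "
      "can reach the outside without moving atoms.")
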