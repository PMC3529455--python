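"""Spatial layout of the emergent groups on the lattice: mottled, not
clumped.

Runs the planar two-group configuration and asks whether group labels
segregate spatially.  The unlike-neighbour fraction is compared with a
label-permutation null: a mottled, interspersed layout sits inside the
null band, whereas two spatial clumps would fall far below it.
"""

from gapcpg.experiments import run_topology_experiment

out = run_topology_experiment(seed=0, n_perm=1000)
grp = out["grouping"]
print(f"groups: {grp.n_groups}, per-group rate {grp.frequency:.2f} Hz")
print(f"unlike-neighbour fraction: {out['mixing_fraction']:.3f} "
      f"(permutation-null percentile {out['null_percentile']:.0f})")

lab = out["lattice"]
print("\nlattice map (rows x cols, '.' = unassigned):")
for r in range(10):
    row = lab[lab.row == r].sort_values("col").label
    print("  " + " ".join("." if l < 0 else str(int(l)) for l in row))
print("\nGroups intersperse across the sheet, so every neuron stays")
print("exposed to both rhythms — the topology-free picture survives.")
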