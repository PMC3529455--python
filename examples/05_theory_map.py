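"""Analytic gap-current treatment: group-count map and connectivity tables.

The average total gap-junction current C * N(R) * g * dV maps any
(connection probability, radius) pair to a predicted group count via the
cutoffs 0.09 / 0.1 / 0.3 nA; in normalized mode all-to-all coverage gives
exactly 1 nA.  The connectivity expectations explain the driver/follower
asymmetry: the larger of two random groups always keeps a larger internal
connection share.
"""

from gapcpg.theory import (TheoryConstants, avg_total_gap_current,
                           prediction_grid, expected_connectivity)

print("all-to-all maximum (normalized):",
      avg_total_gap_current(1.0, None, TheoryConstants()), "nA")

grid = prediction_grid(C_values=[0.1, 0.3, 0.5, 0.7, 1.0],
                       R_values=[1, 2, 3, 5, 10])
print("\npredicted groups over (C, R) — 0 means ungrouped firing:")
print(grid.pivot(index="C_prob", columns="R",
                 values="predicted_groups").to_string())

out = expected_connectivity(0.25, 60, 40)
fr = out["fractions"]
print("\ntwo groups of 60 and 40 at 25% coupling:")
print(f"  expected edges within the larger group: "
      f"{out['counts'][('to_1', 'from_1')]:.1f}")
print(f"  internal connection share: larger {fr[('to_1', 'from_1')]:.2f} "
      f"vs smaller {fr[('to_2', 'from_2')]:.2f}")
print("  -> the larger group drives, the smaller follows, at any size.")
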