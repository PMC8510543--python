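"""Recover a leading/lagging-strand transition asymmetry from a catalog.

Simulates a catalog in which transitions at A:T (and G:C) pairs are twice
as frequent when the diagnostic base (A, or C) templates the lagging
strand (LGST) as when it templates the leading strand (LDST), then
estimates that ratio back from the placement-classified mutations.
"""

from oriconflict import preset, simulate
from oriconflict.reports import placement_summary

res = simulate(preset("strand_bias", seed=0))  # true ratio = 2.0
ps = placement_summary(res.mutations, res.genome)

print("transition placement counts (per-site targets in parentheses):")
for cls in ps["counts"].index:
    print(f"  {cls:<10} {ps['counts'][cls]:>5}  ({ps['site_targets'][cls]:,} sites)")

for name, key in (("A:T", "at_ratio"), ("G:C", "gc_ratio")):
    r, lo, hi = ps[key]
    print(f"{name} LGST/LDST rate ratio: {r:.2f}  (95% CI {lo:.2f}-{hi:.2f})")

print("\nBoth intervals cover the simulated 2-fold bias. Because head-on")
print("genes are transcribed off the LGST, this purely replicative strand")
print("bias would look like an orientation effect if analyzed naively.")
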