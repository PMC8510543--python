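"""Full CD-vs-HO comparison report on a null-scenario catalog.

Simulates the default study conditions (500 kb genome, 500 genes, 200 lines
x 1,000 generations, no orientation effect) and runs the complete report.
Under the null, no comparison should survive Benjamini-Hochberg adjustment.
"""

import tempfile

from oriconflict import preset, simulate
from oriconflict.reports import run_report

res = simulate(preset("null", seed=0))
with tempfile.TemporaryDirectory() as out:
    rep = run_report(res.genome, res.mutations, res.experiments, out, seed=0)

comp = rep["tables"]["table3_comparisons"]
cols = ["metric", "mean_cd", "mean_ho", "delta_ho", "p_t", "p_t_adj", "p_mw_adj"]
print(comp.loc[comp.subset_name == "all_genes", cols].round(3).to_string(index=False))

sig = (comp[["p_t_adj", "p_mw_adj"]] <= 0.05).sum().sum()
print(f"\nBH family size: {rep['manifest']['bh_family_size']}; "
      f"significant orientation comparisons: {sig}")
print("delta_ho is the percent excess of the head-on mean over the")
print("codirectional mean; with no engineered bias it hovers near 0 and")
print("no adjusted p-value clears 0.05.")
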