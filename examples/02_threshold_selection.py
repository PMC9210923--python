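"""Select discovery thresholds whose FDR interval excludes 1, with FCR control.

Runs one simulated study from the validation design (scenario D: 10 signal
blocks with strong effects), computes the per-threshold FDR table, then
applies the three selection rules: the step-up procedure with FCR-adjusted
intervals, and the two naive comparators (CI upper bound < 1; point estimate
< 0.2).  Saves the discovery plot alongside.
"""

from pathlib import Path

from permfdr import run_replicate, scenario
from permfdr.plots import discovery_plot

spec = scenario("D")
rep = run_replicate(spec, rng=42, true_fdr=None if spec.is_global_null else [0.5] * 41)
table = rep.table

by = rep.selections["BY"]
print(f"grid size |T| = {len(table)}, step-up selected R = {by.n_selected} thresholds")
print(f"adjusted interval level alpha* = R*alpha/|T| = {by.alpha_star:.5f}")
print(f"naive selections: UCB {rep.selections['UCB'].n_selected}, "
      f"M.2 {rep.selections['M.2'].n_selected}")

sel = table[table["selected_by"]]
cols = ["neg_log10_t", "S", "fdr", "ci_lower", "ci_upper", "adj_ci_lower", "adj_ci_upper"]
print("\nstep-up-selected thresholds (adjusted intervals are wider when R < |T|):")
print(sel[cols].round(4).to_string(index=False))

out = Path(__file__).with_name("discovery_plot.png")
discovery_plot(table, out=out)
print(f"\ndiscovery plot written to {out}")
print("Selected rows have FDR intervals that exclude 1: at those thresholds some"
      "\ndiscoveries are expected to be true, with the adjustment keeping the"
      "\nexpected fraction of selected intervals missing their FDR at alpha = 0.05.")
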