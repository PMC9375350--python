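"""Stratum increment tables and the repeated-measures comparison.

Simulates the default cohort, computes mean +/- SD child-level ADJCI
per risk stratum at 6, 12 and 18 months under the cavitated (3-6)
cutoff, and tests whether the later increments exceed the 6-month one
(repeated-measures ANOVA, Bonferroni-corrected paired post hocs).
"""

import numpy as np

from carietrack import Cutoff, child_adjci, default_config, rm_anova, simulate
from carietrack.reporting import table_increment_comparison

cohort, _ = simulate(default_config(seed=1))

art, evidence = table_increment_comparison(cohort, use_imputation=True, m=20, seed=1)
t = art.table
t = t[(t["cutoff"] == "3-6") & (t["risk"] != "ALL")]
print("Cutoff 3-6, Rubin-pooled stratum means over 20 hot-deck imputations:")
print(t[["risk", "months", "n", "mean", "sd"]].round(3).to_string(index=False))

print("\nAdjusted p-values feeding the recall rule (per risk, cutoff 3-6):")
for risk in ("LOW", "MEDIUM", "HIGH"):
    p = evidence[(risk, "3-6")]
    print(f"  {risk:6s}  6m: {p[6]:.4f}  12m-vs-6m: {p[12]:.4f}  18m-vs-6m: {p[18]:.4f}")

print("\nIncrements rise with risk at every interval; a small p means the")
print("stratum's caries increment is demonstrable at that interval.")
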