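"""Outcome analysis per assessment group and signature.

For each assessment group with enough deaths: Kaplan-Meier curves and
log-rank tests per signature class, univariable Cox models, and
multivariable Cox models adjusted for tumor size, age, grade and
lymph-node status (dropped automatically where a group is
node-homogeneous), excluding classes below 8% of the group from the
multivariable fits. Writes the forest-plot-ready table to
results/outcome.csv.
"""

import pandas as pd

from sigcordance.models import load_toy_models
from sigcordance.survival import outcome_table, run_outcome_suite

calls = pd.read_csv("results/calls.csv", comment="#", index_col=0)
groups = pd.read_csv("results/groups.csv", comment="#")
models = {m.name: m for m in load_toy_models()}
sigs = [c for c in calls.columns if not c.endswith("_score")]

results = run_outcome_suite(groups, calls, groups["assessment_group"], sigs,
                            models=models)
table = outcome_table(results)
table.to_csv("results/outcome.csv", index=False)

print("group eligibility (>=10 events):")
for g, r in sorted(results.items()):
    print(f"  {g:24s} n={r.n:5d} events={r.events:4d} "
          f"{'kept' if r.eligible else 'excluded'}")

if "hr" in table.columns:
    multi = table[(table.get("analysis") == "multivariable")].dropna(subset=["hr"])
    sig_rows = multi[multi["p"] < 0.05]
    print(f"\nmultivariable Cox: {len(multi)} class contrasts fitted, "
          f"{len(sig_rows)} significant at p<0.05:")
    for _, r in sig_rows.iterrows():
        print(f"  {r['group']:22s} {r['signature']:18s} {r['class']:12s} "
              f"HR {r['hr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}) "
              f"p={r['p']:.3g}")
print("wrote results/outcome.csv")
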