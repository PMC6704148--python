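"""Pairwise agreement and consensus voting between risk signatures.

For every pair of risk-prediction signatures within each assessment
group: exact agreement over all classes, exact agreement after omitting
intermediate-risk calls, agreement-chart geometry for the largest ER+
group, and the unanimous-vote consensus subgroups. Writes agreement
matrices, summaries, chart geometry JSON and consensus fractions under
results/.
"""

import json

import pandas as pd

from sigcordance.concord import (RISK_ORDER, build_agreement_chart,
                                 consensus_summary, consensus_vote,
                                 contingency, pairwise_agreement_matrix)
from sigcordance.models import load_toy_models

calls = pd.read_csv("results/calls.csv", comment="#", index_col=0)
groups = pd.read_csv("results/groups.csv", comment="#")
aligned = groups.set_index("sample_id")["assessment_group"].reindex(calls.index)

models = load_toy_models()
rp = [m.name for m in models if m.is_risk_model]
three_class = [m.name for m in models
               if m.is_risk_model and len(m.risk_labels) == 3]

for mode in ("all_classes", "low_high_only"):
    matrices, summary = pairwise_agreement_matrix(calls, rp, aligned, mode=mode)
    summary.to_csv(f"results/agreement_summary_{mode}.csv", index=False)
    for group, mat in matrices.items():
        mat.to_csv(f"results/agreement_{mode}_{group}.csv")
    print(f"median pairwise agreement per group ({mode}):")
    for _, r in summary.sort_values("median").iterrows():
        print(f"  {r['group']:24s} median {r['median']:5.1f}%  "
              f"range [{r['min']:5.1f}, {r['max']:5.1f}]")

# agreement charts for 3-class pairs in the largest ER+ endocrine-only group
target = "ERPOS_LNNEG_ENDO"
mask = (aligned == target).to_numpy()
charts = {}
for i, s1 in enumerate(three_class):
    for s2 in three_class[i + 1:]:
        tab = contingency(calls.loc[mask, s1], calls.loc[mask, s2], RISK_ORDER)
        charts[f"{s1}|{s2}"] = build_agreement_chart(tab).to_dict()
with open("results/agreement_charts.json", "w") as fh:
    json.dump({"group": target, "charts": charts}, fh, indent=2)

votes = consensus_vote(calls, rp)
summary = consensus_summary(votes, aligned)
summary.to_csv("results/consensus.csv", index=False)
print("\nconsensus voting (unanimous-low fraction per ER+ group):")
low = summary[(summary.vote == "unanimous_low")
              & summary.group.str.startswith("ERPOS")]
for _, r in low.iterrows():
    print(f"  {r['group']:24s} {r['fraction']:.2%} (n={r['count']})")
print("wrote results/agreement_*.csv, agreement_charts.json, consensus.csv")
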