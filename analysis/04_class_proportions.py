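"""Class proportions per signature within each assessment group.

The synthetic analogue of the proportional summaries: within each
clinical assessment group, the fraction of samples per class for every
signature (NA rates reported separately). Writes results/proportions.csv
and prints the modal class per group for the risk models.
"""

import pandas as pd

from sigcordance.models import load_toy_models
from sigcordance.stratify import proportions_by

calls = pd.read_csv("results/calls.csv", comment="#", index_col=0)
groups = pd.read_csv("results/groups.csv", comment="#")
aligned = groups.set_index("sample_id")["assessment_group"].reindex(calls.index)

models = load_toy_models()
label_cols = [m.name for m in models]
props = proportions_by(calls[label_cols], aligned)
props.to_csv("results/proportions.csv", index=False)

rp = [m.name for m in models if m.is_risk_model]
print("modal risk class per assessment group:")
sub = props[props.signature.isin(rp) & (props.stratum != "NONE")]
top = (sub.sort_values("fraction", ascending=False)
       .groupby(["stratum", "signature"]).head(1))
for (stratum, signature), row in top.set_index(["stratum", "signature"]).iterrows():
    print(f"  {stratum:24s} {signature:18s} {row['label']:<12s} "
          f"{row['fraction']:.2f}")
print("wrote results/proportions.csv")
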