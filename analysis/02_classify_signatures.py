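"""Classify the cohort with the bundled toy signature models.

Applies one model per mathematical family (nearest-centroid subtyping,
module-tree subtyping, linear and clipped-linear risk scores, ROR-style
correlation+proliferation+size scores, template-correlation risk calls),
with reference-set median centering where a model requires it. Writes
per-sample calls (and scores for risk models) to results/calls.csv.
"""

import pandas as pd

from sigcordance.models import classify_cohort, load_toy_models
from sigcordance.simulate import read_cohort

cohort = read_cohort("results/cohort")
models = load_toy_models()
calls = classify_cohort(cohort.expression, cohort.clinical, models, seed=1)
calls.to_csv("results/calls.csv")

print(f"classified {len(calls)} samples with {len(models)} toy models")
for m in models:
    counts = calls[m.name].value_counts(dropna=False)
    print(f"  {m.name:18s} ({m.family}): "
          + ", ".join(f"{k}={v}" for k, v in counts.items()))
print("wrote results/calls.csv")
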