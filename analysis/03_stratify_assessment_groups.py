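"""Stratify the cohort into the nine clinical assessment groups.

Groups are defined by IHC markers (ER/PR positive above 10% staining,
HER2), lymph-node status and administered adjuvant treatment; everything
else falls into the NONE catch-all so the assignment partitions the
cohort. Writes results/groups.csv.
"""

import pandas as pd

from sigcordance.stratify import add_assessment_groups

clinical = pd.read_csv("results/cohort/clinical.csv", comment="#")
groups = add_assessment_groups(clinical)
groups.to_csv("results/groups.csv", index=False)

counts = groups["assessment_group"].value_counts()
print(f"assessment groups (n={len(groups)}):")
print(counts.to_string())
print(f"partition check: {counts.sum()} == {len(groups)}")
print("wrote results/groups.csv")
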