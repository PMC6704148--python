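# TOY risk-of-recurrence model (Tot-style variant: correlation-weighted
# subtype term + proliferation + tumor size, lymph-node-dependent cutpoints).
# NON-CLINICAL toy coefficients.
name: ror_toy
family: ror
centroids: centroid5_centroids.tsv
classes: [LumA, LumB, HER2E, Basal, Normal]
correlation_method: pearson
centering: reference_set
variant: Tot
weights:
  LumA: -0.5
  LumB: 0.6
  HER2E: 0.4
  Basal: 0.7
  Normal: -1.0
coefficients: {a: 1.0, b: 0.6, c: 0.2, intercept: 0.0}
proliferation_genes:
  - PROL001
  - PROL002
  - PROL003
  - PROL004
  - PROL005
  - PROL006
  - PROL007
  - PROL008
  - PROL009
  - PROL010
size_unit_mm: 10.0
thresholds:
  LN-: [0.5, 1.5]
  LN+: [0.25, 1.25]
risk_labels: [low, intermediate, high]
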