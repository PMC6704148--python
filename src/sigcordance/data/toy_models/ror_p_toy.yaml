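# TOY risk-of-recurrence model, P-variant (no size term, single cutpoint set).
# NON-CLINICAL toy coefficients.
name: ror_p_toy
family: ror
centroids: centroid5_centroids.tsv
classes: [LumA, LumB, HER2E, Basal, Normal]
correlation_method: pearson
centering: reference_set
variant: P
weights:
  LumA: -0.5
  LumB: 0.6
  HER2E: 0.4
  Basal: 0.7
  Normal: -1.0
coefficients: {a: 1.0, b: 0.6, intercept: 0.0}
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
thresholds: [0.0, 1.0]
risk_labels: [low, intermediate, high]
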