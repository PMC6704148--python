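# TOY 70-gene-style two-class risk model: correlation to a good-outcome
# template profile. NON-CLINICAL toy parameters.
name: gene70_toy
family: correlation_risk
template: gene70_template.tsv
correlation_method: pearson
centering: reference_set
threshold: 0.0
risk_labels: [low, high]
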