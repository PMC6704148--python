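# TOY recurrence-score-style linear risk model with clip-at-zero module
# terms and a 0-100 rescaled output. NON-CLINICAL toy coefficients.
name: recurrence21_toy
family: linear_risk
centering: reference_set
modules:
  - name: proliferation
    genes:
      - PROL031
      - PROL032
      - PROL033
      - PROL034
      - PROL035
      - PROL036
      - PROL037
      - PROL038
      - PROL039
      - PROL040
      - PROL041
      - PROL042
      - PROL043
      - PROL044
      - PROL045
    beta: 1.4
    clip: true
    clip_threshold: 0.0
  - name: her2
    genes:
      - HER2009
      - HER2010
      - HER2011
      - HER2012
      - HER2013
      - HER2014
      - HER2015
      - HER2016
    beta: 0.5
    clip: true
    clip_threshold: 0.0
  - name: er
    genes:
      - ER021
      - ER022
      - ER023
      - ER024
      - ER025
      - ER026
      - ER027
      - ER028
      - ER029
      - ER030
    beta: -0.6
intercept: 0.0
raw_range: [-2.0, 4.0]
output_range: [0.0, 100.0]
thresholds: [40.0, 60.0]
risk_labels: [low, intermediate, high]
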