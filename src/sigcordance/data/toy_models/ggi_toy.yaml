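# TOY genomic-grade-style linear risk model: proliferation-dominated
# weighted module score. NON-CLINICAL toy coefficients.
name: ggi_toy
family: linear_risk
centering: reference_set
modules:
  - name: proliferation
    genes:
      - PROL011
      - PROL012
      - PROL013
      - PROL014
      - PROL015
      - PROL016
      - PROL017
      - PROL018
      - PROL019
      - PROL020
      - PROL021
      - PROL022
      - PROL023
      - PROL024
      - PROL025
      - PROL026
      - PROL027
      - PROL028
      - PROL029
      - PROL030
    beta: 1.0
  - name: er
    genes:
      - ER011
      - ER012
      - ER013
      - ER014
      - ER015
      - ER016
      - ER017
      - ER018
      - ER019
      - ER020
    beta: -0.4
intercept: 0.0
thresholds: [0.0, 0.8]
risk_labels: [low, intermediate, high]
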