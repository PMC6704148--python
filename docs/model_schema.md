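# Signature model file schema

A signature model is one YAML file, optionally referencing a TSV of
centroids or a template profile (paths are resolved relative to the YAML
file). Unknown fields are rejected at load time. Common fields:

| field | type | notes |
|---|---|---|
| `name` | string | defaults to the file stem |
| `family` | string | `centroid_subtype`, `linear_risk`, `ror`, `module_subtype`, `correlation_risk` |
| `genes` | list | optional; inferred from centroids/modules when omitted |
| `centering` | `none` \| `reference_set` | reference-set median centering before scoring |
| `correlation_method` | `spearman` \| `pearson` | default spearman |
| `risk_labels` | list | ordered low → high; default `[low, intermediate, high]` |

Centroid TSV format: first column = class name, header row = gene ids,
one row per class (a template profile is a centroid TSV with one row).

## centroid_subtype

```yaml
family: centroid_subtype
centroids: centroids.tsv
classes: [LumA, LumB, HER2E, Basal, Normal]   # declared order = tie-break order
correlation_method: spearman
centering: reference_set
```

## linear_risk

```yaml
family: linear_risk
modules:
  - {name: proliferation, genes: [...], beta: 1.4, clip: true, clip_threshold: 0.0}
  - {name: er, genes: [...], beta: -0.6}
intercept: 0.0
raw_range: [-2.0, 4.0]        # optional affine rescale (give both or neither)
output_range: [0.0, 100.0]
thresholds: [40.0, 60.0]      # strictly increasing; len + 1 == len(risk_labels)
```

## ror

```yaml
family: ror
centroids: centroids.tsv
classes: [LumA, LumB, HER2E, Basal, Normal]
variant: Tot                   # S | P | T | PT | Tot
weights: {LumA: -0.5, LumB: 0.6, HER2E: 0.4, Basal: 0.7, Normal: -1.0}
coefficients: {a: 1.0, b: 0.6, c: 0.2, intercept: 0.0}
proliferation_genes: [...]     # required for P/PT/Tot
size_unit_mm: 10.0             # size term = size_mm / size_unit_mm (T/PT/Tot)
thresholds:                    # scalar list, or keyed by lymph-node status
  LN-: [0.5, 1.5]
  LN+: [0.25, 1.25]
```

## correlation_risk

```yaml
family: correlation_risk
template: template.tsv         # exactly one row
threshold: 0.0                 # low risk iff correlation >= threshold
risk_labels: [low, high]
```

## module_subtype

```yaml
family: module_subtype
modules: {er: [...], her2: [...], proliferation: [...]}
cuts: {er: 0.0, her2: 1.0, proliferation: 0.5}
classes:                       # decision-tree leaf names
  her2: HER2-like
  luminal_low: LumA-like
  luminal_high: LumB-like
  basal: Basal-like
```

To transcribe a published signature, place its gene identifiers,
centroids/weights and cutpoints into the matching family schema. The
bundled `src/sigcordance/data/toy_models/` sets are synthetic toys for
pipeline exercise only and carry no published coefficients.
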