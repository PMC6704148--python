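# Example pipeline configuration: full synthetic run with plots.
# Run:  sigcordance run --config pipeline.yaml
out_dir: results/pipeline
seed: 1
simulate: true
sim:
  n_samples: 3520
plots: true
min_events: 10
min_class_fraction: 0.08
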