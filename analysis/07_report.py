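"""Render the markdown summary report from the pipeline outputs.

Runs the orchestrated pipeline (which re-executes all stages under one
config with provenance headers) into results/pipeline/ and renders
report.md from the CSV outputs alone.
"""

from sigcordance.pipeline import PipelineConfig, render_report, run_pipeline

config = PipelineConfig(out_dir="results/pipeline", seed=1, plots=True)
bundle = run_pipeline(config)
path = render_report("results/pipeline")
print(f"pipeline bundle: {len(bundle)} outputs, config hash "
      f"{config.config_hash()}")
print(f"report: {path}")
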