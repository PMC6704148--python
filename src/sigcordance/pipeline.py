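"""Pipeline orchestration: simulate -> classify -> stratify -> concord ->
survive, driven by one YAML config, with provenance and a markdown report.

Every output file embeds the config hash and seed in a leading ``#``
comment line; re-running with the same config reproduces the outputs
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concord import (build_agreement_chart, consensus_summary, consensus_vote,
                      contingency, pairwise_agreement_matrix)
from .matrix import ExpressionMatrix
from .models import load_models, load_toy_models, toy_model_dir
from .simulate import SimParams, default_params, generate_cohort, read_cohort, write_cohort
from .stratify import add_assessment_groups, proportions_by
from .survival import outcome_table, run_outcome_suite

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    # inputs: either simulate (sim overrides SimParams fields) or load paths
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    expression: str | None = None
    clinical: str | None = None
    model_dir: str | None = None          # None -> bundled toy models
    # stage toggles
    run_classify: bool = True
    run_stratify: bool = True
    run_proportions: bool = True
    run_concordance: bool = True
    run_voting: bool = True
    run_outcome: bool = True
    plots: bool = False
    concordance_modes: list[str] = field(
        default_factory=lambda: ["all_classes", "low_high_only"])
    voting_panel: list[str] | None = None  # None -> all RP signatures
    min_events: int = 10
    min_class_fraction: float = 0.08

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise PipelineError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for key in ("expression", "clinical"):
                p = getattr(self, key)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"config: {key} path not resolvable: {p}")
        if self.model_dir is not None and not Path(self.model_dir).exists():
            raise PipelineError(f"config: model_dir not resolvable: {self.model_dir}")
        for mode in self.concordance_modes:
            if mode not in ("all_classes", "low_high_only"):
                raise PipelineError(f"config: unknown concordance mode {mode!r}")

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output location is
        excluded: the same analysis written elsewhere is the same run)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canonical = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return f"sigcordance {__version__} config={config.config_hash()} seed={config.seed}"


def _write_csv(frame: pd.DataFrame, path: Path, header: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, **kw)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute enabled stages in order; returns the output bundle paths.

    A stage failure halts the run with a stage-attributed message; the
    manifest is written first so partial outputs are identifiable.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    bundle: dict[str, Path] = {}

    manifest = {
        "package": "sigcordance", "version": __version__,
        "config_hash": config.config_hash(), "seed": config.seed,
        "config": asdict(config),
    }
    bundle["manifest"] = out / "manifest.json"
    bundle["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")

    models = (load_toy_models() if config.model_dir is None
              else load_models(sorted(Path(config.model_dir).glob("*.yaml"))))
    if not models and config.run_classify:
        raise PipelineError("classify: no model files found")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc

    # --- cohort ---
    if config.simulate:
        def _sim():
            params = default_params(**{**config.sim, "seed": config.seed})
            cohort = generate_cohort(params)
            paths = write_cohort(cohort, out / "cohort", header_comment=header)
            return cohort, paths
        cohort, paths = stage("simulate", _sim)
        bundle.update({f"cohort_{k}": v for k, v in paths.items()})
    else:
        def _load():
            expr = ExpressionMatrix.read_tsv(config.expression)
            clinical = pd.read_csv(config.clinical, comment="#")
            from .simulate import Cohort
            return Cohort(expression=expr, clinical=clinical)
        cohort = stage("load", _load)

    calls = groups_df = None

    if config.run_classify:
        def _classify():
            table = classify = None
            from .models import classify_cohort
            table = classify_cohort(cohort.expression, cohort.clinical, models,
                                    seed=config.seed)
            _write_csv(table, out / "calls.csv", header)
            return table
        calls = stage("classify", _classify)
        bundle["calls"] = out / "calls.csv"

    if config.run_stratify:
        def _stratify():
            g = add_assessment_groups(cohort.clinical)
            _write_csv(g, out / "groups.csv", header, index=False)
            return g
        groups_df = stage("stratify", _stratify)
        bundle["groups"] = out / "groups.csv"

    rp_sigs = [m.name for m in models if m.is_risk_model]
    group_series = (groups_df.set_index("sample_id")["assessment_group"]
                    if groups_df is not None else None)

    if config.run_proportions and calls is not None and group_series is not None:
        def _props():
            label_cols = [m.name for m in models if m.name in calls.columns]
            props = proportions_by(calls[label_cols],
                                   group_series.reindex(calls.index))
            _write_csv(props, out / "proportions.csv", header, index=False)
            return props
        stage("proportions", _props)
        bundle["proportions"] = out / "proportions.csv"

    if config.run_concordance and calls is not None and group_series is not None:
        def _concord():
            from .concord import RISK_ORDER
            aligned = group_series.reindex(calls.index)
            for mode in config.concordance_modes:
                matrices, summary = pairwise_agreement_matrix(
                    calls, rp_sigs, aligned, mode=mode)
                _write_csv(summary, out / f"agreement_summary_{mode}.csv",
                           header, index=False)
                bundle[f"agreement_summary_{mode}"] = out / f"agreement_summary_{mode}.csv"
                for group, mat in matrices.items():
                    p = out / f"agreement_{mode}_{group}.csv"
                    _write_csv(mat, p, header)
                    bundle[f"agreement_{mode}_{group}"] = p
            # agreement-chart geometry for every 3-class RP pair, largest group
            charts = {}
            three_class = [m.name for m in models
                           if m.is_risk_model and len(m.risk_labels) == 3]
            sizes = aligned[aligned != "NONE"].value_counts()
            if len(sizes) and len(three_class) >= 2:
                top = sizes.index[0]
                mask = (aligned == top).to_numpy()
                for i, s1 in enumerate(three_class):
                    for s2 in three_class[i + 1:]:
                        try:
                            tab = contingency(calls.loc[mask, s1],
                                              calls.loc[mask, s2], RISK_ORDER)
                        except ValueError:
                            continue
                        geom = build_agreement_chart(tab)
                        charts[f"{top}:{s1}|{s2}"] = geom.to_dict()
                        if config.plots:
                            from .plots import agreement_chart_svg
                            agreement_chart_svg(
                                geom, out / f"chart_{s1}_vs_{s2}.svg",
                                xlabel=s2, ylabel=s1)
            p = out / "agreement_charts.json"
            p.write_text(json.dumps({"provenance": header, "charts": charts},
                                    indent=2) + "\n")
            bundle["agreement_charts"] = p
        stage("concordance", _concord)

    if config.run_voting and calls is not None and group_series is not None:
        def _vote():
            panel = config.voting_panel or rp_sigs
            votes = consensus_vote(calls, panel)
            summary = consensus_summary(votes, group_series.reindex(calls.index))
            _write_csv(summary, out / "consensus.csv", header, index=False)
        stage("voting", _vote)
        bundle["consensus"] = out / "consensus.csv"

    if config.run_outcome and calls is not None and groups_df is not None:
        def _outcome():
            label_cols = [m.name for m in models if m.name in calls.columns]
            results = run_outcome_suite(
                groups_df, calls, groups_df["assessment_group"], label_cols,
                models={m.name: m for m in models},
                min_events=config.min_events,
                min_class_fraction=config.min_class_fraction)
            table = outcome_table(results)
            _write_csv(table, out / "outcome.csv", header, index=False)
            if config.plots and not table.empty and "hr" in table:
                from .plots import forest_svg
                multi = table[table.get("analysis") == "multivariable"]
                for group in multi["group"].unique():
                    forest_svg(multi[multi["group"] == group],
                               out / f"forest_{group}.svg", title=str(group))
            return results
        stage("outcome", _outcome)
        bundle["outcome"] = out / "outcome.csv"

    return bundle


def render_report(out_dir) -> Path:
    """Render a markdown summary from the CSV outputs (no recomputation).

    Sections whose stage outputs are missing are marked absent.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("render_report: manifest.json missing; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# sigcordance pipeline report",
        "",
        f"- package version: {manifest['version']}",
        f"- config hash: `{manifest['config_hash']}`, seed: {manifest['seed']}",
        "",
    ]

    def read(name):
        p = out / name
        return pd.read_csv(p, comment="#") if p.exists() else None

    groups = read("groups.csv")
    lines.append("## Assessment groups")
    if groups is None:
        lines.append("*(section absent: groups.csv not found)*")
    else:
        counts = groups["assessment_group"].value_counts()
        lines.append("")
        lines.append("| group | n |")
        lines.append("|---|---|")
        for g, n in counts.items():
            lines.append(f"| {g} | {n} |")

    props = read("proportions.csv")
    lines.append("\n## Class proportions per assessment group")
    if props is None:
        lines.append("*(section absent: proportions.csv not found)*")
    else:
        shown = props[props["stratum"] != "NONE"]
        if shown.empty:
            lines.append("*(all samples in NONE; nothing to summarize)*")
        else:
            top = (shown.sort_values("fraction", ascending=False)
                   .groupby(["stratum", "signature"]).head(1))
            lines.append("")
            lines.append("| group | signature | modal class | fraction |")
            lines.append("|---|---|---|---|")
            for _, r in top.iterrows():
                lines.append(f"| {r['stratum']} | {r['signature']} | {r['label']} "
                             f"| {r['fraction']:.2f} |")

    for mode in ("all_classes", "low_high_only"):
        summary = read(f"agreement_summary_{mode}.csv")
        lines.append(f"\n## Pairwise agreement ({mode})")
        if summary is None:
            lines.append("*(section absent)*")
        elif summary.empty:
            lines.append("*(no groups with enough usable samples)*")
        else:
            lines.append("")
            lines.append("| group | median % | min % | max % |")
            lines.append("|---|---|---|---|")
            for _, r in summary.iterrows():
                lines.append(f"| {r['group']} | {r['median']:.1f} | {r['min']:.1f} "
                             f"| {r['max']:.1f} |")

    consensus = read("consensus.csv")
    lines.append("\n## Consensus risk voting")
    if consensus is None:
        lines.append("*(section absent)*")
    else:
        lines.append("")
        lines.append("| group | vote | fraction |")
        lines.append("|---|---|---|")
        for _, r in consensus[consensus["group"] != "NONE"].iterrows():
            frac = "" if pd.isna(r["fraction"]) else f"{r['fraction']:.3f}"
            lines.append(f"| {r['group']} | {r['vote']} | {frac} |")

    outcome = read("outcome.csv")
    lines.append("\n## Outcome analyses")
    if outcome is None:
        lines.append("*(section absent)*")
    elif "hr" not in outcome.columns:
        lines.append("*(no eligible groups)*")
    else:
        multi = outcome.dropna(subset=["hr"])
        multi = multi[multi["analysis"] == "multivariable"]
        lines.append("")
        lines.append("| group | signature | class | HR (95% CI) | p |")
        lines.append("|---|---|---|---|---|")
        for _, r in multi.iterrows():
            lines.append(f"| {r['group']} | {r['signature']} | {r['class']} | "
                         f"{r['hr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}) | "
                         f"{r['p']:.3g} |")

    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
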