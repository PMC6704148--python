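"""Seeded synthetic breast-cancer cohort generator.

The generator emulates the statistical structure of a population-based
primary breast-cancer RNA-seq cohort so every downstream analysis stage
(classification, stratification, concordance, survival) can be exercised
and tested without any external download:

* a latent intrinsic molecular subtype per tumor (luminal A/B,
  HER2-enriched, basal-like, normal-like) drives correlated expression
  blocks along four biological axes (estrogen receptor signalling, HER2
  amplicon, proliferation, basal keratins);
* IHC markers (ER %, PR %, HER2 status) are drawn consistently with the
  latent subtype, with a small subtype-conditional discordance rate;
* adjuvant treatment is assigned from registry-style percentages
  conditional on the IHC marker group (no confounding by indication);
* overall survival is exponential under proportional hazards tied to a
  latent risk score (the standardized proliferation-axis mean), with
  administrative censoring at the follow-up horizon.

Everything is driven by one integer seed: the same :class:`SimParams`
produce a bit-identical :class:`Cohort`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DEFAULT_LOG_OFFSET, ExpressionMatrix

SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal")
AXES = ("er", "her2", "proliferation", "basal")

# Which expression axes are switched on in each latent subtype.
AXIS_ACTIVATION: dict[str, dict[str, int]] = {
    "LumA": {"er": 1, "her2": 0, "proliferation": 0, "basal": 0},
    "LumB": {"er": 1, "her2": 0, "proliferation": 1, "basal": 0},
    "HER2E": {"er": 0, "her2": 1, "proliferation": 1, "basal": 0},
    "Basal": {"er": 0, "her2": 0, "proliferation": 1, "basal": 1},
    "Normal": {"er": 0, "her2": 0, "proliferation": 0, "basal": 0},
}

# Adjuvant treatment regimen -> (endocrine, chemotherapy, anti-HER2) flags.
REGIMEN_FLAGS: dict[str, tuple[int, int, int]] = {
    "endocrine_only": (1, 0, 0),
    "act_only": (0, 1, 0),
    "endocrine_act": (1, 1, 0),
    "antiher2_act": (0, 1, 1),
    "antiher2_act_endocrine": (1, 1, 1),
    "untreated": (0, 0, 0),
    "other": (1, 0, 1),  # rare mixed regimens outside the named groups
}

# Registry-style treatment percentages per IHC marker group (columns of the
# cohort characteristics table); normalized at sampling time.
DEFAULT_TREATMENT_PROBS: dict[str, dict[str, float]] = {
    "ERpos_LNpos": {
        "endocrine_only": 48.0, "act_only": 1.0, "endocrine_act": 49.0,
        "antiher2_act": 0.0, "antiher2_act_endocrine": 0.7,
        "untreated": 1.6, "other": 0.0,
    },
    "ERpos_LNneg": {
        "endocrine_only": 71.0, "act_only": 0.0, "endocrine_act": 15.0,
        "antiher2_act": 0.0, "antiher2_act_endocrine": 0.0,
        "untreated": 13.0, "other": 1.0,
    },
    "HER2pos_ERpos": {
        "endocrine_only": 17.0, "act_only": 0.0, "endocrine_act": 2.5,
        "antiher2_act": 2.0, "antiher2_act_endocrine": 74.0,
        "untreated": 3.0, "other": 1.5,
    },
    "HER2pos_ERneg": {
        "endocrine_only": 1.0, "act_only": 1.0, "endocrine_act": 0.0,
        "antiher2_act": 79.0, "antiher2_act_endocrine": 6.0,
        "untreated": 8.0, "other": 5.0,
    },
    "TNBC": {
        "endocrine_only": 1.0, "act_only": 70.0, "endocrine_act": 1.0,
        "antiher2_act": 1.0, "antiher2_act_endocrine": 0.0,
        "untreated": 24.0, "other": 3.0,
    },
}

# P(ER IHC > 10% | latent subtype). Chosen so that under the default subtype
# mix the implied ER+ marginal equals the 84.2% registry target; the non-unit
# probabilities for luminal tumors and the non-zero basal probability are the
# IHC-vs-subtype discordance seen in real cohorts.
DEFAULT_ER_POS_PROB = {"LumA": 0.98, "LumB": 0.98, "HER2E": 0.72,
                       "Basal": 0.10, "Normal": 0.97}
DEFAULT_HER2_POS_PROB = {"LumA": 0.04, "LumB": 0.04, "HER2E": 0.85,
                         "Basal": 0.02, "Normal": 0.02}

# Nottingham grade distribution per latent subtype (grade 1/2/3).
DEFAULT_GRADE_PROBS = {
    "LumA": (0.25, 0.60, 0.15),
    "LumB": (0.05, 0.40, 0.55),
    "HER2E": (0.02, 0.28, 0.70),
    "Basal": (0.01, 0.14, 0.85),
    "Normal": (0.30, 0.55, 0.15),
}


@dataclass
class ClinicalMarginals:
    """Target marginal distributions for the simulated clinical table.

    Defaults approximate a Swedish population-based registry cohort:
    median age 65 (range 25-100), median tumor size 17 mm, 59% node
    negative, 84.2% ER+ (IHC > 10%), 13.2% HER2+.
    """

    age_mean: float = 65.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (25.0, 100.0)
    size_log_mean: float = math.log(17.0)
    size_log_sd: float = 0.55
    size_range: tuple[float, float] = (1.0, 126.0)
    ln_zero_frac: float = 0.59
    er_pos_target: float = 0.842
    her2_pos_target: float = 0.132
    er_pos_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ER_POS_PROB))
    her2_pos_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HER2_POS_PROB))
    pr_pos_given_er_pos: float = 0.87
    pr_pos_given_er_neg: float = 0.04
    grade_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_PROBS))
    treatment_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_TREATMENT_PROBS.items()})


@dataclass
class SimParams:
    """Parameters of the synthetic cohort generator."""

    n_samples: int = 3520
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {"LumA": 0.45, "LumB": 0.20, "HER2E": 0.12,
                                 "Basal": 0.12, "Normal": 0.11})
    n_genes: int = 500
    genes_per_axis: dict[str, int] = field(
        default_factory=lambda: {"er": 40, "her2": 25,
                                 "proliferation": 50, "basal": 30})
    axis_effect: float = 2.0        # log2 shift of an activated axis
    noise_sd: float = 1.0           # log2-scale iid noise
    log_offset: float = DEFAULT_LOG_OFFSET
    ihc_flip_prob: float = 0.0      # extra symmetric ER-IHC flip noise
    clinical_marginals: ClinicalMarginals = field(default_factory=ClinicalMarginals)
    baseline_hazard: float = 0.03   # events per year at risk score 0
    log_hazard_per_risk_unit: float = 0.8
    followup_years: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_proportions sum to {total}, expected 1")
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if any(c <= 0 for c in self.genes_per_axis.values()):
            raise ValueError("genes_per_axis counts must be positive")
        if sum(self.genes_per_axis.values()) > self.n_genes:
            raise ValueError("axis genes exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if unknown := set(self.subtype_proportions) - set(SUBTYPES):
            raise ValueError(f"unknown subtypes: {sorted(unknown)}")


@dataclass
class Cohort:
    """A generated cohort: expression, clinical table and generating truth.

    ``truth`` records the latent subtype and latent risk per sample, for
    recovery tests only; analysis stages never read it.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.clinical["sample_id"]) != list(self.expression.sample_ids):
            raise ValueError("clinical sample_ids do not match expression order")


def default_params(**overrides) -> SimParams:
    """Default generator parameters approximating the registry cohort margins.

    Keyword overrides replace top-level :class:`SimParams` fields.
    """
    return dataclasses.replace(SimParams(), **overrides) if overrides else SimParams()


def gene_names(params: SimParams) -> tuple[list[str], dict[str, list[str]]]:
    """Deterministic gene identifiers and the axis -> genes map."""
    names: list[str] = []
    axis_genes: dict[str, list[str]] = {}
    prefixes = {"er": "ER", "her2": "HER2", "proliferation": "PROL", "basal": "BAS"}
    for axis in AXES:
        genes = [f"{prefixes[axis]}{i:03d}" for i in range(1, params.genes_per_axis[axis] + 1)]
        axis_genes[axis] = genes
        names.extend(genes)
    n_bg = params.n_genes - len(names)
    names.extend(f"BG{i:04d}" for i in range(1, n_bg + 1))
    return names, axis_genes


def _subtype_assignments(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    subtypes = [s for s in SUBTYPES if params.subtype_proportions.get(s, 0) > 0]
    probs = np.array([params.subtype_proportions[s] for s in subtypes])
    draws = rng.choice(len(subtypes), size=params.n_samples, p=probs / probs.sum())
    assigned = np.array(subtypes)[draws]
    counts = pd.Series(assigned).value_counts()
    low = [s for s in subtypes if counts.get(s, 0) < 2]
    if low:
        raise ValueError(
            f"fewer than 2 samples drawn for subtype(s) {low}; "
            "increase n_samples or remove the subtype (reference centering "
            "is undefined for singleton strata)")
    return assigned


def subtype_mean_profiles(params: SimParams) -> pd.DataFrame:
    """Noise-free mean expression profile per subtype (genes x subtypes).

    The per-gene baseline is drawn deterministically from the seed so that
    profiles, cohorts and the matching true-centroid model all agree.
    """
    names, axis_genes = gene_names(params)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 7]))
    baseline = rng.normal(3.0, 1.0, size=len(names))
    prof = pd.DataFrame({s: baseline.copy() for s in SUBTYPES}, index=names)
    gene_pos = {g: i for i, g in enumerate(names)}
    for subtype in SUBTYPES:
        for axis, active in AXIS_ACTIVATION[subtype].items():
            if active:
                rows = [gene_pos[g] for g in axis_genes[axis]]
                prof.iloc[rows, prof.columns.get_loc(subtype)] += params.axis_effect
    return prof


def _draw_clinical(params: SimParams, subtypes: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    cm = params.clinical_marginals
    n = params.n_samples

    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n), *cm.age_range)
    size = np.clip(rng.lognormal(cm.size_log_mean, cm.size_log_sd, n), *cm.size_range)

    er_p = np.array([cm.er_pos_prob[s] for s in subtypes])
    er_pos = rng.random(n) < er_p
    if params.ihc_flip_prob > 0:
        er_pos ^= rng.random(n) < params.ihc_flip_prob
    er_pct = np.where(er_pos, rng.uniform(20, 100, n), rng.uniform(0, 10, n))

    pr_p = np.where(er_pos, cm.pr_pos_given_er_pos, cm.pr_pos_given_er_neg)
    pr_pos = rng.random(n) < pr_p
    pr_pct = np.where(pr_pos, rng.uniform(11, 100, n), rng.uniform(0, 10, n))

    her2_p = np.array([cm.her2_pos_prob[s] for s in subtypes])
    her2 = (rng.random(n) < her2_p).astype(int)

    grade_mat = np.array([cm.grade_probs[s] for s in subtypes])
    grade = 1 + (rng.random(n)[:, None] > np.cumsum(grade_mat, axis=1)).sum(axis=1)

    ln_positive = rng.random(n) >= cm.ln_zero_frac
    n_nodes = np.zeros(n, dtype=int)
    many = rng.random(n) < 0.25  # among LN+, a quarter have >=4 nodes
    n_nodes[ln_positive & ~many] = rng.integers(1, 4, int((ln_positive & ~many).sum()))
    n_nodes[ln_positive & many] = rng.integers(4, 13, int((ln_positive & many).sum()))

    # Marker group column used for registry-style treatment assignment.
    groups = np.where(
        her2 == 1,
        np.where(er_pos, "HER2pos_ERpos", "HER2pos_ERneg"),
        np.where(er_pos,
                 np.where(n_nodes >= 1, "ERpos_LNpos", "ERpos_LNneg"),
                 "TNBC"))
    regimens = np.empty(n, dtype=object)
    regimen_names = list(REGIMEN_FLAGS)
    for g in np.unique(groups):
        mask = groups == g
        weights = np.array([cm.treatment_probs[g].get(r, 0.0) for r in regimen_names])
        weights = weights / weights.sum()
        regimens[mask] = rng.choice(regimen_names, size=int(mask.sum()), p=weights)
    flags = np.array([REGIMEN_FLAGS[r] for r in regimens])

    return pd.DataFrame({
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "age_years": np.round(age, 1),
        "size_mm": np.round(size, 1),
        "nhg": grade,
        "ln_pos_nodes": n_nodes,
        "er_ihc_pct": np.round(er_pct, 1),
        "pr_ihc_pct": np.round(pr_pct, 1),
        "her2": her2,
        "treat_endo": flags[:, 0],
        "treat_act": flags[:, 1],
        "treat_antiher2": flags[:, 2],
    })


def generate_cohort(params: SimParams) -> Cohort:
    """Generate a seeded synthetic cohort.

    Expression = subtype mean profile + Normal(0, noise_sd) noise on the
    log2(FPKM + offset) scale. The latent risk is the cohort-standardized
    proliferation-axis mean; overall survival is exponential with hazard
    ``baseline_hazard * exp(log_hazard_per_risk_unit * risk)`` and
    administrative censoring at ``followup_years``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    subtypes = _subtype_assignments(params, rng)

    profiles = subtype_mean_profiles(params)
    names = list(profiles.index)
    means = profiles[subtypes].to_numpy()  # genes x samples
    noise = rng.normal(0.0, params.noise_sd, size=means.shape) if params.noise_sd > 0 \
        else np.zeros_like(means)
    values = means + noise

    clinical = _draw_clinical(params, subtypes, rng)
    expr = ExpressionMatrix(names, list(clinical["sample_id"]), values)

    _, axis_genes = gene_names(params)
    prol_rows = [names.index(g) for g in axis_genes["proliferation"]]
    prol_mean = values[prol_rows].mean(axis=0)
    sd = prol_mean.std(ddof=0)
    risk = (prol_mean - prol_mean.mean()) / (sd if sd > 0 else 1.0)

    hazard = params.baseline_hazard * np.exp(params.log_hazard_per_risk_unit * risk)
    latent_time = rng.exponential(1.0 / hazard)
    os_event = (latent_time < params.followup_years).astype(int)
    os_years = np.minimum(latent_time, params.followup_years)

    clinical["os_years"] = np.round(os_years, 4)
    clinical["os_event"] = os_event

    truth = pd.DataFrame({
        "sample_id": clinical["sample_id"],
        "subtype": subtypes,
        "risk": risk,
    })
    return Cohort(expression=expr, clinical=clinical, truth=truth)


def write_cohort(cohort: Cohort, out_dir, header_comment: str | None = None) -> dict[str, Path]:
    """Write expression.tsv, clinical.csv and (if present) truth.csv.

    The truth table is written to a separate file that analysis stages
    never read. ``header_comment`` is prepended as a ``#`` line for
    provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv", "clinical": out / "clinical.csv"}

    def _write(frame_writer, path):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            frame_writer(fh)

    _write(lambda fh: cohort.expression.to_frame()
           .rename_axis("gene_id").to_csv(fh, sep="\t", float_format="%.6g"),
           paths["expression"])
    _write(lambda fh: cohort.clinical.to_csv(fh, index=False), paths["clinical"])
    if cohort.truth is not None:
        paths["truth"] = out / "truth.csv"
        _write(lambda fh: cohort.truth.to_csv(fh, index=False, float_format="%.6g"),
               paths["truth"])
    return paths


def read_cohort(in_dir, with_truth: bool = False) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    expr = ExpressionMatrix.read_tsv(in_dir / "expression.tsv")
    clinical = pd.read_csv(in_dir / "clinical.csv", comment="#")
    truth = None
    truth_path = in_dir / "truth.csv"
    if with_truth and truth_path.exists():
        truth = pd.read_csv(truth_path, comment="#")
    return Cohort(expression=expr, clinical=clinical, truth=truth)


def true_centroid_model(params: SimParams):
    """Nearest-centroid subtype model built from the generator's own mean
    profiles over the axis genes (for planted-subtype recovery tests)."""
    from .models import SignatureModel

    profiles = subtype_mean_profiles(params)
    _, axis_genes = gene_names(params)
    genes = [g for gs in axis_genes.values() for g in gs]
    centroids = profiles.loc[genes].T  # classes x genes
    return SignatureModel(
        name="true_centroids",
        family="centroid_subtype",
        genes=genes,
        classes=list(SUBTYPES),
        centroids=centroids,
        correlation_method="spearman",
        centering="none",
    )
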