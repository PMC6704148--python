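"""Parameterized multigene signature models and classification operations.

Five mathematical families cover the published subtype and risk-prediction
signatures:

``centroid_subtype``
    nearest-centroid molecular subtyping: a sample is assigned the class
    whose reference expression profile it correlates with most strongly
    (Spearman by default).
``linear_risk``
    weighted sums of gene-module mean expression, with optional
    clip-at-zero terms, mimicking recurrence-score-style predictors.
``ror``
    risk-of-recurrence scores: weighted centroid correlations plus
    optional proliferation and tumor-size terms, with risk cutpoints that
    may depend on lymph-node status (variants S/P/T/PT/Tot).
``correlation_risk``
    correlation to a single good-outcome template profile with one
    cutpoint (70-gene-style two-class calls).
``module_subtype``
    a fixed decision tree over ER/HER2/proliferation module scores
    (SCMOD2-style subtyping).

Models are external config artifacts (YAML plus centroid TSV); the
repository ships self-consistent *toy* parameter sets for every family.
No published coefficient set is re-derived or claimed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("centroid_subtype", "linear_risk", "ror", "module_subtype",
            "correlation_risk")
ROR_VARIANTS = ("S", "P", "T", "PT", "Tot")
RISK_LABELS_3 = ("low", "intermediate", "high")
NA = None  # labels use None / np.nan for missing


class ModelLoadError(ValueError):
    """Raised when a signature model file violates its schema."""


@dataclass
class LinearModule:
    name: str
    genes: list[str]
    beta: float
    clip: bool = False
    clip_threshold: float = 0.0


@dataclass
class SignatureModel:
    """A loaded, validated signature classifier."""

    name: str
    family: str
    genes: list[str]
    classes: list[str] | None = None          # subtype class order (tie-break order)
    centroids: pd.DataFrame | None = None     # classes x genes
    risk_labels: list[str] = field(default_factory=lambda: list(RISK_LABELS_3))
    thresholds: list[float] | dict[str, list[float]] | None = None
    centering: str = "none"                   # none | reference_set
    correlation_method: str = "spearman"      # spearman | pearson
    # linear_risk
    modules: list[LinearModule] | None = None
    intercept: float = 0.0
    raw_range: tuple[float, float] | None = None
    output_range: tuple[float, float] | None = None
    # ror
    variant: str | None = None
    weights: dict[str, float] | None = None   # per-centroid-class weight
    coefficients: dict[str, float] | None = None  # a, b, c, intercept
    proliferation_genes: list[str] | None = None
    size_unit_mm: float = 10.0                # size_term = size_mm / size_unit_mm
    # correlation_risk
    threshold: float | None = None
    # module_subtype
    module_genes: dict[str, list[str]] | None = None
    module_cuts: dict[str, float] | None = None
    tree_classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelLoadError(f"{self.name}: unknown family '{self.family}'")
        if self.centering not in ("none", "reference_set"):
            raise ModelLoadError(f"{self.name}: bad centering '{self.centering}'")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ModelLoadError(
                f"{self.name}: bad correlation_method '{self.correlation_method}'")
        if self.thresholds is not None:
            groups = (self.thresholds.values()
                      if isinstance(self.thresholds, dict) else [self.thresholds])
            for ts in groups:
                if any(b <= a for a, b in zip(ts, ts[1:])):
                    raise ModelLoadError(
                        f"{self.name}: thresholds must be strictly increasing, got {ts}")
                if len(ts) + 1 != len(self.risk_labels):
                    raise ModelLoadError(
                        f"{self.name}: {len(ts)} thresholds need "
                        f"{len(ts) + 1} risk_labels, have {len(self.risk_labels)}")
        if self.centroids is not None:
            missing = set(self.centroids.columns) - set(self.genes)
            if missing:
                raise ModelLoadError(
                    f"{self.name}: centroid genes missing from genes: {sorted(missing)[:5]}")

    @property
    def is_risk_model(self) -> bool:
        return self.family in ("linear_risk", "ror", "correlation_risk")

    @property
    def low_risk_label(self) -> str:
        return self.risk_labels[0]


_COMMON_KEYS = {"name", "family", "genes", "centering", "correlation_method",
                "risk_labels"}
_FAMILY_KEYS = {
    "centroid_subtype": {"centroids", "classes"},
    "linear_risk": {"modules", "intercept", "raw_range", "output_range",
                    "thresholds"},
    "ror": {"centroids", "classes", "variant", "weights", "coefficients",
            "proliferation_genes", "size_unit_mm", "thresholds"},
    "correlation_risk": {"template", "threshold"},
    "module_subtype": {"modules", "cuts", "classes"},
}


def _read_centroids(spec, base: Path, name: str) -> pd.DataFrame:
    """Centroid TSV: rows = classes, columns = genes."""
    if isinstance(spec, str):
        path = base / spec
        if not path.exists():
            raise ModelLoadError(f"{name}: centroids file not found: {path}")
        return pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(spec, dict):  # inline {class: {gene: value}}
        return pd.DataFrame(spec).T
    raise ModelLoadError(f"{name}: field 'centroids' must be a path or mapping")


def load_signature_model(path) -> SignatureModel:
    """Load and validate a signature model from a YAML file.

    Unknown fields are rejected; schema violations raise
    :class:`ModelLoadError` naming the offending field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelLoadError(f"{path}: model file must contain a mapping")
    name = raw.get("name", path.stem)
    family = raw.get("family")
    if family not in FAMILIES:
        raise ModelLoadError(f"{name}: field 'family' must be one of {FAMILIES}, "
                             f"got {family!r}")
    allowed = _COMMON_KEYS | _FAMILY_KEYS[family]
    unknown = set(raw) - allowed
    if unknown:
        raise ModelLoadError(f"{name}: unknown field(s) {sorted(unknown)}")

    base = path.parent
    kw: dict = {"name": name, "family": family}
    for key in ("centering", "correlation_method"):
        if key in raw:
            kw[key] = raw[key]
    if "risk_labels" in raw:
        kw["risk_labels"] = list(raw["risk_labels"])

    genes: list[str] = list(raw.get("genes", []))

    if family in ("centroid_subtype", "ror"):
        if "centroids" not in raw:
            raise ModelLoadError(f"{name}: family {family} requires field 'centroids'")
        centroids = _read_centroids(raw["centroids"], base, name)
        classes = list(raw.get("classes", centroids.index))
        if set(classes) != set(centroids.index):
            raise ModelLoadError(f"{name}: field 'classes' does not match centroid rows")
        kw["centroids"] = centroids.loc[classes]
        kw["classes"] = classes
        genes = genes or list(centroids.columns)

    if family == "ror":
        variant = raw.get("variant")
        if variant not in ROR_VARIANTS:
            raise ModelLoadError(
                f"{name}: field 'variant' must be one of {ROR_VARIANTS}, got {variant!r}")
        weights = raw.get("weights")
        if not isinstance(weights, dict) or set(weights) != set(kw["classes"]):
            raise ModelLoadError(f"{name}: field 'weights' must map every centroid class")
        coeffs = dict(raw.get("coefficients", {}))
        for c in coeffs:
            if c not in ("a", "b", "c", "intercept"):
                raise ModelLoadError(f"{name}: unknown coefficient '{c}'")
        kw.update(variant=variant, weights={k: float(v) for k, v in weights.items()},
                  coefficients={k: float(v) for k, v in coeffs.items()},
                  size_unit_mm=float(raw.get("size_unit_mm", 10.0)))
        prol = raw.get("proliferation_genes")
        if variant in ("P", "PT", "Tot") and not prol:
            raise ModelLoadError(
                f"{name}: variant {variant} requires field 'proliferation_genes'")
        if prol:
            kw["proliferation_genes"] = list(prol)
            genes = genes + [g for g in prol if g not in genes]
        kw["thresholds"] = _parse_thresholds(raw.get("thresholds"), name)

    if family == "linear_risk":
        mods_raw = raw.get("modules")
        if not mods_raw:
            raise ModelLoadError(f"{name}: family linear_risk requires field 'modules'")
        modules = []
        for m in mods_raw:
            extra = set(m) - {"name", "genes", "beta", "clip", "clip_threshold"}
            if extra:
                raise ModelLoadError(f"{name}: unknown module field(s) {sorted(extra)}")
            modules.append(LinearModule(
                name=m["name"], genes=list(m["genes"]), beta=float(m["beta"]),
                clip=bool(m.get("clip", False)),
                clip_threshold=float(m.get("clip_threshold", 0.0))))
        kw["modules"] = modules
        kw["intercept"] = float(raw.get("intercept", 0.0))
        for key in ("raw_range", "output_range"):
            if key in raw:
                lo, hi = raw[key]
                if not hi > lo:
                    raise ModelLoadError(f"{name}: field '{key}' must be (lo, hi) with hi > lo")
                kw[key] = (float(lo), float(hi))
        if ("raw_range" in kw) != ("output_range" in kw):
            raise ModelLoadError(f"{name}: raw_range and output_range must be given together")
        kw["thresholds"] = _parse_thresholds(raw.get("thresholds"), name)
        genes = genes or sorted({g for m in modules for g in m.genes})

    if family == "correlation_risk":
        if "template" not in raw:
            raise ModelLoadError(f"{name}: family correlation_risk requires field 'template'")
        template = _read_centroids(raw["template"], base, name)
        if len(template) != 1:
            raise ModelLoadError(f"{name}: field 'template' must have exactly one row")
        if "threshold" not in raw:
            raise ModelLoadError(f"{name}: family correlation_risk requires field 'threshold'")
        kw["centroids"] = template
        kw["threshold"] = float(raw["threshold"])
        kw.setdefault("risk_labels", ["low", "high"])
        if "risk_labels" in raw and len(raw["risk_labels"]) != 2:
            raise ModelLoadError(f"{name}: correlation_risk needs exactly 2 risk_labels")
        kw["risk_labels"] = kw.get("risk_labels", ["low", "high"])
        genes = genes or list(template.columns)

    if family == "module_subtype":
        mods = raw.get("modules")
        cuts = raw.get("cuts")
        classes = raw.get("classes")
        if not isinstance(mods, dict) or set(mods) != {"er", "her2", "proliferation"}:
            raise ModelLoadError(
                f"{name}: field 'modules' must map er/her2/proliferation to gene lists")
        needed = {"her2", "luminal_low", "luminal_high", "basal"}
        if not isinstance(classes, dict) or set(classes) != needed:
            raise ModelLoadError(f"{name}: field 'classes' must map {sorted(needed)}")
        if not isinstance(cuts, dict) or set(cuts) != {"er", "her2", "proliferation"}:
            raise ModelLoadError(f"{name}: field 'cuts' must map er/her2/proliferation")
        kw["module_genes"] = {k: list(v) for k, v in mods.items()}
        kw["module_cuts"] = {k: float(v) for k, v in cuts.items()}
        kw["tree_classes"] = dict(classes)
        kw["classes"] = [classes["her2"], classes["luminal_low"],
                         classes["luminal_high"], classes["basal"]]
        genes = genes or sorted({g for gs in mods.values() for g in gs})

    kw["genes"] = genes
    return SignatureModel(**kw)


def _parse_thresholds(spec, name):
    if spec is None:
        return None
    if isinstance(spec, dict):
        bad = set(spec) - {"LN-", "LN+"}
        if bad:
            raise ModelLoadError(f"{name}: threshold keys must be 'LN-'/'LN+', got {sorted(bad)}")
        return {k: [float(t) for t in v] for k, v in spec.items()}
    return [float(t) for t in spec]


# ---------------------------------------------------------------------------
# operations


def center_genes(X: ExpressionMatrix, reference_samples: list[str]) -> ExpressionMatrix:
    """Subtract the per-gene median over a reference sample set.

    Reference-set centering removes cohort-composition bias before
    centroid correlation; after centering the reference-set median of
    every gene is exactly 0.
    """
    if len(reference_samples) == 0:
        raise ValueError("empty reference set")
    if len(reference_samples) < 2:
        raise ValueError("reference set must contain at least 2 samples")
    pos = {s: j for j, s in enumerate(X.sample_ids)}
    missing = [s for s in reference_samples if s not in pos]
    if missing:
        raise KeyError(f"reference samples not in matrix: {missing[:5]}")
    cols = [pos[s] for s in reference_samples]
    medians = np.median(X.values[:, cols], axis=1, keepdims=True)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), X.values - medians)


def choose_reference_set(clinical: pd.DataFrame, size: int = 100,
                         er_pos_fraction: float = 0.5, seed: int = 0) -> list[str]:
    """Seeded ER-stratified reference subsample for gene centering.

    Balancing ER status mimics composition-controlled reference sets used
    with single-cohort centroid classification; the fraction is
    configurable because published descriptions leave it open.
    """
    rng = np.random.default_rng(seed)
    er_pos = clinical["er_ihc_pct"] > 10
    pos_ids = clinical.loc[er_pos, "sample_id"].to_numpy()
    neg_ids = clinical.loc[~er_pos, "sample_id"].to_numpy()
    n_pos = min(len(pos_ids), int(round(size * er_pos_fraction)))
    n_neg = min(len(neg_ids), size - n_pos)
    chosen = np.concatenate([
        rng.choice(pos_ids, size=n_pos, replace=False) if n_pos else [],
        rng.choice(neg_ids, size=n_neg, replace=False) if n_neg else [],
    ])
    return sorted(chosen.tolist())


def _corr_matrix(values: np.ndarray, centroids: np.ndarray,
                 method: str = "spearman") -> np.ndarray:
    """Correlations of every sample column with every centroid row.

    ``values`` is genes x samples, ``centroids`` classes x genes (same
    gene order). Returns classes x samples. Spearman uses average ranks
    (ties handled as in scipy); undefined correlations (constant sample
    or centroid) are NaN. Vectorized equivalent of calling
    :func:`correlation_profile` per sample.
    """
    if method == "spearman":
        xv = stats.rankdata(values, axis=0)
        cv = stats.rankdata(centroids, axis=1)
    else:
        xv = values.astype(float)
        cv = centroids.astype(float)
    xz = xv - xv.mean(axis=0, keepdims=True)
    cz = cv - cv.mean(axis=1, keepdims=True)
    xs = np.sqrt((xz ** 2).sum(axis=0))  # per sample
    cs = np.sqrt((cz ** 2).sum(axis=1))  # per class
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cz @ xz) / np.outer(cs, xs)
    corr[:, xs == 0] = np.nan
    corr[cs == 0, :] = np.nan
    return corr


def correlation_profile(x: pd.Series, centroids: pd.DataFrame,
                        method: str = "spearman") -> pd.Series:
    """Correlate one sample's expression with each class centroid.

    Returns one correlation in [-1, 1] per class; NaN where undefined
    (constant centroid or sample). Fewer than 3 shared genes yields an
    all-NaN vector with a logged warning.
    """
    shared = [g for g in centroids.columns if g in x.index]
    out = pd.Series(np.nan, index=centroids.index, dtype=float)
    if len(shared) < 3:
        logger.warning("correlation_profile: only %d shared genes", len(shared))
        return out
    xv = x[shared].to_numpy(dtype=float)
    if not np.all(np.isfinite(xv)):
        return out
    for cls in centroids.index:
        cv = centroids.loc[cls, shared].to_numpy(dtype=float)
        if np.ptp(cv) == 0 or np.ptp(xv) == 0:
            continue
        if method == "spearman":
            r = stats.spearmanr(xv, cv).statistic
        else:
            r = stats.pearsonr(xv, cv).statistic
        out[cls] = r
    return out


def _argmax_label(corr: pd.Series, classes: list[str]):
    """First class (declared order) attaining the maximum correlation."""
    vals = corr[classes]
    if vals.isna().all():
        return np.nan
    best = vals.max()
    for cls in classes:
        if vals[cls] == best:
            return cls
    return np.nan


def _model_correlations(X: ExpressionMatrix, model: SignatureModel,
                        classes: list[str]) -> np.ndarray:
    """classes x samples correlation matrix over the model's shared genes."""
    present = set(X.gene_ids)
    shared = [g for g in model.centroids.columns if g in present]
    if len(shared) < 3:
        logger.warning("%s: only %d shared genes; all calls NA", model.name, len(shared))
        return np.full((len(classes), X.n_samples), np.nan)
    sub = X.subset_genes(shared)
    cent = model.centroids.loc[classes, shared].to_numpy(dtype=float)
    return _corr_matrix(sub.values, cent, model.correlation_method)


def classify_centroid(X: ExpressionMatrix, model: SignatureModel) -> pd.Series:
    """Nearest-centroid subtype call per sample (argmax correlation).

    ``X`` must already be reference-set centered when the model requires
    it. Ties break to the first class in declared order; undefined
    correlations propagate NaN.
    """
    if model.family != "centroid_subtype":
        raise ValueError(f"{model.name} is not a centroid_subtype model")
    corr = _model_correlations(X, model, model.classes)
    labels = []
    for j in range(X.n_samples):
        col = corr[:, j]
        if np.isnan(col).all():
            labels.append(np.nan)
        else:
            labels.append(model.classes[int(np.nanargmax(col))])
    return pd.Series(labels, index=X.sample_ids, name=model.name)


def _module_means(X: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """Per-sample mean expression over a gene module (NaN if none present)."""
    shared = X.shared_genes(genes)
    if not shared:
        return np.full(X.n_samples, np.nan)
    return X.subset_genes(shared).values.mean(axis=0)


def score_ror(X: ExpressionMatrix, model: SignatureModel,
              clinical: pd.DataFrame | None = None,
              variant: str | None = None) -> pd.Series:
    """Risk-of-recurrence score per sample.

    ROR-S = sum_k w_k * r_k over subtype-centroid correlations r;
    variants add a proliferation term b*P (P = mean expression of the
    proliferation module) and/or a size term c*(size_mm / size_unit_mm):

    score = a*ROR-S [+ b*P] [+ c*size_term] + intercept

    The Tot variant is scored like PT; its lymph-node-dependent cutpoints
    apply at risk assignment. Missing tumor size for a size-using variant
    yields NaN with a logged note.
    """
    if model.family != "ror":
        raise ValueError(f"{model.name} is not a ror model")
    variant = variant or model.variant
    if variant not in ROR_VARIANTS:
        raise ValueError(f"unknown ROR variant {variant!r}")
    coeffs = model.coefficients or {}
    a = coeffs.get("a", 1.0)
    b = coeffs.get("b", 0.0)
    c = coeffs.get("c", 0.0)
    intercept = coeffs.get("intercept", 0.0)
    use_p = variant in ("P", "PT", "Tot")
    use_t = variant in ("T", "PT", "Tot")

    classes = list(model.centroids.index)
    corr = _model_correlations(X, model, classes)  # classes x samples
    w = np.array([model.weights[k] for k in classes])
    ror_s = w @ np.where(np.isnan(corr), 0.0, corr)
    ror_s[np.isnan(corr).any(axis=0)] = np.nan
    if variant == "S":
        return pd.Series(ror_s, index=X.sample_ids, name=f"{model.name}_score")

    total = a * ror_s
    if use_p:
        total = total + b * _module_means(X, model.proliferation_genes)
    if use_t:
        if clinical is None or "size_mm" not in clinical:
            raise ValueError(f"{model.name}: variant {variant} needs clinical size_mm")
        sizes = clinical.set_index("sample_id")["size_mm"].reindex(X.sample_ids)
        if sizes.isna().any():
            logger.info("score_ror %s: missing tumor size for %d sample(s)",
                        model.name, int(sizes.isna().sum()))
        total = total + c * (sizes.to_numpy(dtype=float) / model.size_unit_mm)
    return pd.Series(total + intercept, index=X.sample_ids, name=f"{model.name}_score")


def score_linear(X: ExpressionMatrix, model: SignatureModel) -> pd.Series:
    """Weighted module-mean risk score with optional clip-at-zero terms.

    score = intercept + sum_m beta_m * f_m, where f_m is the module's mean
    expression, replaced by max(f_m - tau_m, 0) for clipped modules; an
    optional affine rescale maps a declared raw range onto an output range
    (clamped at the range ends).
    """
    if model.family != "linear_risk":
        raise ValueError(f"{model.name} is not a linear_risk model")
    total = np.full(X.n_samples, float(model.intercept))
    for mod in model.modules:
        f = _module_means(X, mod.genes)
        if mod.clip:
            f = np.maximum(f - mod.clip_threshold, 0.0)
        total = total + mod.beta * f
    if model.raw_range is not None:
        r0, r1 = model.raw_range
        o0, o1 = model.output_range
        total = o0 + (total - r0) * (o1 - o0) / (r1 - r0)
        total = np.clip(total, min(o0, o1), max(o0, o1))
    return pd.Series(total, index=X.sample_ids, name=f"{model.name}_score")


def classify_correlation_risk(X: ExpressionMatrix, model: SignatureModel) -> pd.Series:
    """Two-class risk call by correlation to a good-outcome template:
    low risk iff correlation >= threshold."""
    if model.family != "correlation_risk":
        raise ValueError(f"{model.name} is not a correlation_risk model")
    low, high = model.risk_labels
    corr = _model_correlations(X, model, list(model.centroids.index))[0]
    labels = [np.nan if np.isnan(r) else (low if r >= model.threshold else high)
              for r in corr]
    return pd.Series(labels, index=X.sample_ids, name=model.name)


def classify_modules(X: ExpressionMatrix, model: SignatureModel,
                     clinical: pd.DataFrame | None = None) -> pd.Series:
    """Deterministic decision tree over ER/HER2/proliferation module scores.

    HER2 module >= cut => HER2 class; else ER module >= cut => luminal,
    split by the proliferation cut into low/high-proliferation classes;
    else the basal-like class. Missing module genes give NaN.
    """
    if model.family != "module_subtype":
        raise ValueError(f"{model.name} is not a module_subtype model")
    cuts, cls = model.module_cuts, model.tree_classes
    m = {k: _module_means(X, genes) for k, genes in model.module_genes.items()}
    labels = []
    for j in range(X.n_samples):
        if any(np.isnan(m[k][j]) for k in m):
            labels.append(np.nan)
        elif m["her2"][j] >= cuts["her2"]:
            labels.append(cls["her2"])
        elif m["er"][j] >= cuts["er"]:
            labels.append(cls["luminal_high"] if m["proliferation"][j] >= cuts["proliferation"]
                          else cls["luminal_low"])
        else:
            labels.append(cls["basal"])
    return pd.Series(labels, index=X.sample_ids, name=model.name)


def assign_risk(scores: pd.Series, model: SignatureModel,
                clinical: pd.DataFrame | None = None) -> pd.Series:
    """Map numeric scores to ordered risk labels via the model cutpoints.

    Boundary convention: a score equal to a cutpoint takes the higher
    class. Thresholds may be keyed by lymph-node status (``LN-``/``LN+``),
    in which case ``clinical`` must supply ``ln_pos_nodes``. NaN scores
    (or NaN LN status with keyed thresholds) give NaN labels.
    """
    if model.thresholds is None:
        raise ValueError(f"{model.name}: no thresholds defined")
    ln_keyed = isinstance(model.thresholds, dict)
    ln = None
    if ln_keyed:
        if clinical is None or "ln_pos_nodes" not in clinical:
            raise ValueError(f"{model.name}: LN-keyed thresholds need clinical ln_pos_nodes")
        ln = clinical.set_index("sample_id")["ln_pos_nodes"]

    def one(sid, score):
        if pd.isna(score):
            return np.nan
        if ln_keyed:
            nodes = ln.get(sid, np.nan)
            if pd.isna(nodes):
                return np.nan
            ts = model.thresholds["LN+" if nodes >= 1 else "LN-"]
        else:
            ts = model.thresholds
        k = sum(score >= t for t in ts)
        return model.risk_labels[k]

    return pd.Series({sid: one(sid, s) for sid, s in scores.items()}, name=model.name)


def classify_cohort(X: ExpressionMatrix, clinical: pd.DataFrame,
                    models: list[SignatureModel],
                    reference_samples: list[str] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Run every model on a cohort; one label column per model.

    Risk models additionally retain a ``<name>_score`` column. A model
    that fails produces an all-NaN column and a logged error rather than
    aborting the table. Models declaring ``centering: reference_set`` are
    applied to the reference-median-centered matrix (the reference set is
    a seeded ER-stratified subsample unless supplied).
    """
    table = pd.DataFrame(index=pd.Index(X.sample_ids, name="sample_id"))
    centered = None
    if any(m.centering == "reference_set" for m in models):
        if reference_samples is None:
            reference_samples = choose_reference_set(clinical, seed=seed)
        centered = center_genes(X, reference_samples)

    for model in models:
        Xm = centered if model.centering == "reference_set" else X
        try:
            if model.family == "centroid_subtype":
                table[model.name] = classify_centroid(Xm, model)
            elif model.family == "module_subtype":
                table[model.name] = classify_modules(Xm, model, clinical)
            elif model.family == "correlation_risk":
                table[model.name] = classify_correlation_risk(Xm, model)
            elif model.family == "linear_risk":
                scores = score_linear(Xm, model)
                table[f"{model.name}_score"] = scores
                table[model.name] = assign_risk(scores, model, clinical)
            elif model.family == "ror":
                scores = score_ror(Xm, model, clinical)
                table[f"{model.name}_score"] = scores
                table[model.name] = assign_risk(scores, model, clinical)
        except Exception:
            logger.exception("model %s failed; column set to NA", model.name)
            table[model.name] = np.nan
    return table


def load_models(paths) -> list[SignatureModel]:
    return [load_signature_model(p) for p in paths]


def toy_model_dir() -> Path:
    """Directory of the bundled toy (non-clinical) signature models."""
    return Path(__file__).parent / "data" / "toy_models"


def load_toy_models() -> list[SignatureModel]:
    return load_models(sorted(toy_model_dir().glob("*.yaml")))
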