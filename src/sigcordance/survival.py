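"""Outcome analysis: Kaplan-Meier curves, log-rank tests and Cox
proportional-hazards models per signature class within assessment groups.

The endpoint is a generic (time, event) pair labeled overall survival
(OS); no competing risks. Estimation is delegated to lifelines
(product-limit estimator, k-sample log-rank, Cox partial likelihood with
Efron tie handling); this module owns the study design around the fits:
per-class hazard ratios against the signature's low-risk reference class,
the small-class exclusion rule (classes below 8% of the group are left
out of multivariable models), group eligibility by event count, and
automatic dropping of degenerate covariates (e.g. lymph-node status in a
node-homogeneous group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_years", "size_mm", "ln_pos", "nhg")
DEFAULT_MIN_EVENTS = 10
DEFAULT_MIN_CLASS_FRACTION = 0.08


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray        # event-time grid (starts at 0)
    survival: np.ndarray     # S(t), non-increasing, in [0, 1]
    at_risk: np.ndarray      # subjects at risk entering each time
    censor_times: np.ndarray
    n: int
    events: int


@dataclass
class ClassHR:
    label: str
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    """Per-class hazard ratios vs a reference class from a Cox PH fit."""

    reference_class: str
    class_hrs: list[ClassHR]
    covariate_coefs: dict[str, float]
    n: int
    events: int
    n_dropped: int            # complete-case exclusions
    converged: bool
    covariate_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    dropped_covariates: list[str] = field(default_factory=list)
    note: str = ""


def km_estimate(times, events, group_labels=None) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate, per group when labels are given.

    Empty groups are skipped with a log entry; NA labels are ignored.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative times")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    if group_labels is None:
        group_labels = pd.Series(["all"] * len(times))
    groups = pd.Series(list(group_labels))
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups.dropna()):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            logger.info("km_estimate: empty group %r skipped", g)
            continue
        t, e = times[mask], events[mask]
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(g))
        table = kmf.event_table
        out[str(g)] = KMCurve(
            label=str(g),
            times=table.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            at_risk=table["at_risk"].to_numpy(dtype=float),
            censor_times=np.sort(t[e == 0]),
            n=int(mask.sum()),
            events=int(e.sum()),
        )
    return out


def logrank(times, events, group_labels) -> tuple[float, float]:
    """Unweighted k-sample log-rank test; chi-square with k-1 df.

    Returns (statistic, p-value). Fewer than two non-empty groups is an
    error.
    """
    groups = pd.Series(list(group_labels))
    keep = groups.notna().to_numpy()
    times = np.asarray(times, dtype=float)[keep]
    events = np.asarray(events, dtype=int)[keep]
    groups = groups[keep]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def class_size_filter(class_labels, min_fraction: float = DEFAULT_MIN_CLASS_FRACTION
                      ) -> tuple[list[str], list[str]]:
    """Split classes into (retained, dropped) by group-share.

    Classes *smaller than* ``min_fraction`` of the non-NA labels are
    dropped (a class at exactly the threshold is retained).
    """
    labels = pd.Series(list(class_labels)).dropna()
    if labels.empty:
        raise ValueError("no non-NA class labels")
    frac = labels.value_counts(normalize=True)
    retained = [c for c, f in frac.items() if f >= min_fraction]
    dropped = [c for c, f in frac.items() if f < min_fraction]
    if not retained:
        logger.info("class_size_filter: all classes below %.0f%%", 100 * min_fraction)
    return retained, dropped


def _prepare_grade(series: pd.Series, treatment: str = "categorical") -> pd.DataFrame:
    """Grade covariate: categorical dummies (grade 1 reference) or ordinal."""
    if treatment == "ordinal":
        return series.astype(float).to_frame("nhg")
    out = pd.DataFrame(index=series.index)
    for g in (2, 3):
        out[f"nhg_{g}"] = (series == g).astype(float)
    return out


def cox_fit(records: pd.DataFrame, class_labels: pd.Series,
            covariates: tuple[str, ...] = (), reference_class: str | None = None,
            grade_treatment: str = "categorical", alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit of signature class (plus covariates).

    Complete-case: rows with NA in any used column are dropped and
    counted. Constant columns (e.g. LN status in an LN-homogeneous group)
    are removed with a note. Non-convergence / separation is flagged in
    the result, never silent. Ties use the Efron approximation
    (lifelines' default).
    """
    labels = pd.Series(list(class_labels), index=records.index)
    df = pd.DataFrame({
        "duration": records["os_years"].astype(float),
        "event": records["os_event"].astype(int),
    }, index=records.index)
    df["_class"] = labels

    cov_frames = []
    for cov in covariates:
        if cov == "ln_pos":
            cov_frames.append((records["ln_pos_nodes"] >= 1)
                              .astype(float).to_frame("ln_pos"))
        elif cov == "nhg":
            cov_frames.append(_prepare_grade(records["nhg"], grade_treatment))
        else:
            cov_frames.append(records[cov].astype(float).to_frame(cov))
    # Mark NA sources before concat so complete-case counting is exact.
    for cov in covariates:
        src = "ln_pos_nodes" if cov == "ln_pos" else cov
        df.loc[records[src].isna(), "_class"] = np.nan
    X = pd.concat([df] + cov_frames, axis=1)

    n_total = len(X)
    X = X.dropna()
    n_dropped = n_total - len(X)

    present = list(pd.unique(X["_class"]))
    if reference_class is None or reference_class not in present:
        reference_class = present[0] if reference_class is None else reference_class
    if reference_class not in present:
        raise ValueError(f"reference class {reference_class!r} absent from data")
    contrast = [c for c in present if c != reference_class]
    for c in contrast:
        X[f"class_{c}"] = (X["_class"] == c).astype(float)
    X = X.drop(columns="_class")

    events = int(X["event"].sum())
    if events < 1:
        raise ValueError("Cox fit requires at least one event")

    dropped_covs = [c for c in X.columns
                    if c not in ("duration", "event") and X[c].nunique() <= 1]
    X = X.drop(columns=dropped_covs)

    note = ""
    class_cols = [f"class_{c}" for c in contrast if f"class_{c}" in X.columns]
    if not class_cols:
        note = "no class contrast (single class after filtering)"

    converged = True
    cph = CoxPHFitter(alpha=alpha)
    try:
        if X.shape[1] > 2:
            cph.fit(X, duration_col="duration", event_col="event",
                    fit_options={"precision": 1e-9})
            summary = cph.summary
        else:
            summary = pd.DataFrame()
            note = note or "no covariates to fit"
            converged = False
    except (ConvergenceError, Exception) as exc:  # lifelines raises several types
        logger.warning("cox_fit failed to converge: %s", exc)
        converged = False
        summary = pd.DataFrame()
        note = note or f"non-converged: {exc}"

    class_hrs = []
    cov_coefs = {}
    cov_cis = {}
    pct = f"{100 * (1 - alpha):g}%"
    for name, row in summary.iterrows():
        if name.startswith("class_"):
            class_hrs.append(ClassHR(
                label=name[len("class_"):],
                hr=float(row["exp(coef)"]),
                ci_low=float(row[f"exp(coef) lower {pct}"]),
                ci_high=float(row[f"exp(coef) upper {pct}"]),
                p=float(row["p"])))
        else:
            cov_coefs[name] = float(row["coef"])
            cov_cis[name] = (float(row[f"coef lower {pct}"]),
                             float(row[f"coef upper {pct}"]))

    return CoxResult(reference_class=reference_class, class_hrs=class_hrs,
                     covariate_coefs=cov_coefs, covariate_cis=cov_cis,
                     n=int(len(X)), events=events,
                     n_dropped=n_dropped, converged=converged,
                     dropped_covariates=dropped_covs, note=note)


@dataclass
class SignatureOutcome:
    signature: str
    km: dict[str, KMCurve]
    logrank_stat: float
    logrank_p: float
    univariable: CoxResult | None
    multivariable: CoxResult | None
    dropped_classes: list[str]
    note: str = ""


@dataclass
class GroupOutcome:
    group: str
    n: int
    events: int
    eligible: bool
    signatures: dict[str, SignatureOutcome] = field(default_factory=dict)


def run_outcome_suite(clinical: pd.DataFrame, calls: pd.DataFrame,
                      groups: pd.Series, signatures: list[str],
                      models: dict | None = None,
                      min_events: int = DEFAULT_MIN_EVENTS,
                      min_class_fraction: float = DEFAULT_MIN_CLASS_FRACTION,
                      covariates: tuple[str, ...] = DEFAULT_COVARIATES
                      ) -> dict[str, GroupOutcome]:
    """Full outcome analysis per assessment group and signature.

    For each eligible group (>= ``min_events`` events): KM curves and
    log-rank per signature class, univariable Cox (class only) and
    multivariable Cox with the clinical covariates, applying the
    small-class exclusion (< ``min_class_fraction`` of the group) to the
    multivariable model. The LN covariate is dropped automatically where
    the group is LN-homogeneous. ``models`` may map signature name ->
    :class:`~sigcordance.models.SignatureModel` to supply the low-risk
    reference class.
    """
    clin = clinical.set_index("sample_id")
    calls = calls.reindex(clin.index)
    groups = pd.Series(np.asarray(groups), index=clin.index)
    results: dict[str, GroupOutcome] = {}

    for group in pd.unique(groups.dropna()):
        mask = groups == group
        sub = clin[mask]
        events = int(sub["os_event"].sum())
        eligible = events >= min_events
        gout = GroupOutcome(group=str(group), n=int(mask.sum()),
                            events=events, eligible=eligible)
        results[str(group)] = gout
        if not eligible:
            logger.info("group %s ineligible (%d events < %d)", group, events, min_events)
            continue
        for sig in signatures:
            labels = calls.loc[mask, sig]
            non_na = labels.dropna()
            if non_na.nunique() < 1:
                continue
            reference = None
            if models and sig in models and models[sig].is_risk_model:
                reference = models[sig].low_risk_label
            sout = _one_signature(sub, labels, sig, reference,
                                  min_class_fraction, covariates)
            gout.signatures[sig] = sout
    return results


def _one_signature(sub: pd.DataFrame, labels: pd.Series, sig: str,
                   reference: str | None, min_class_fraction: float,
                   covariates: tuple[str, ...]) -> SignatureOutcome:
    km = km_estimate(sub["os_years"], sub["os_event"], labels)
    note = ""
    non_na = labels.dropna()
    if non_na.nunique() >= 2:
        lr_stat, lr_p = logrank(sub["os_years"], sub["os_event"], labels)
    else:
        lr_stat, lr_p = np.nan, np.nan
        note = "single class; log-rank and Cox contrasts skipped"

    uni = multi = None
    dropped: list[str] = []
    if non_na.nunique() >= 2:
        ref = reference if reference in set(non_na) else None
        try:
            uni = cox_fit(sub, labels, covariates=(), reference_class=ref)
        except ValueError as exc:
            note = f"univariable: {exc}"
        retained, dropped = class_size_filter(labels, min_class_fraction)
        keep = labels.isin(retained)
        if labels[keep].dropna().nunique() >= 2:
            ref_m = ref if ref in retained else None
            try:
                multi = cox_fit(sub[keep.to_numpy()], labels[keep],
                                covariates=covariates, reference_class=ref_m)
            except ValueError as exc:
                note = f"multivariable: {exc}"
        else:
            note = note or "multivariable skipped: <2 classes after size filter"
    return SignatureOutcome(signature=sig, km=km, logrank_stat=lr_stat,
                            logrank_p=lr_p, univariable=uni, multivariable=multi,
                            dropped_classes=dropped, note=note)


def outcome_table(results: dict[str, GroupOutcome]) -> pd.DataFrame:
    """Flatten outcome results into a forest-plot-ready table."""
    rows = []
    for group, gout in results.items():
        if not gout.eligible:
            rows.append({"group": group, "n": gout.n, "events": gout.events,
                         "eligible": False})
            continue
        for sig, sout in gout.signatures.items():
            base = {"group": group, "n": gout.n, "events": gout.events,
                    "eligible": True, "signature": sig,
                    "logrank_stat": sout.logrank_stat, "logrank_p": sout.logrank_p,
                    "dropped_classes": ";".join(sout.dropped_classes)}
            for kind, res in (("univariable", sout.univariable),
                              ("multivariable", sout.multivariable)):
                if res is None:
                    continue
                for hr in res.class_hrs:
                    rows.append({**base, "analysis": kind, "class": hr.label,
                                 "reference": res.reference_class, "hr": hr.hr,
                                 "ci_low": hr.ci_low, "ci_high": hr.ci_high,
                                 "p": hr.p, "n_fit": res.n, "events_fit": res.events,
                                 "converged": res.converged})
            if sout.univariable is None and sout.multivariable is None:
                rows.append({**base, "analysis": "none", "class": np.nan})
    return pd.DataFrame(rows)
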