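"""Clinical marker derivation and assessment-group stratification.

Patients are partitioned into nine *clinical assessment groups* defined by
IHC marker status (ER/PR at the Swedish IHC cutoff of >10% staining, HER2),
lymph-node status and administered adjuvant treatment, plus a NONE
catch-all so the assignment is always a partition of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ER_PR_IHC_CUTOFF = 10.0  # percent staining; positive means strictly greater


class AssessmentGroup(str, Enum):
    TNBC_ACT = "TNBC_ACT"
    TNBC_UNTREATED = "TNBC_UNTREATED"
    HER2_ERNEG_HER2ACT = "HER2_ERNEG_HER2ACT"
    HER2_ERPOS_HER2ACT_ENDO = "HER2_ERPOS_HER2ACT_ENDO"
    ERPOS_LNNEG_ENDO = "ERPOS_LNNEG_ENDO"
    ERPOS_LNNEG_ENDO_ACT = "ERPOS_LNNEG_ENDO_ACT"
    ERPOS_LNPOS_ENDO = "ERPOS_LNPOS_ENDO"
    ERPOS_LNPOS_ENDO_ACT = "ERPOS_LNPOS_ENDO_ACT"
    ERPOS_LNNEG_UNTREATED = "ERPOS_LNNEG_UNTREATED"
    NONE = "NONE"


NINE_GROUPS = [g for g in AssessmentGroup if g is not AssessmentGroup.NONE]


@dataclass
class Markers:
    """Derived IHC/pathology flags; None encodes not-assessable."""

    er_pos: bool | None
    pr_pos: bool | None
    her2_pos: bool | None
    tnbc: bool | None
    ln_pos: bool | None


def _flag(value, predicate):
    if pd.isna(value):
        return None
    return bool(predicate(value))


def derive_markers(record, submicro_is_positive: bool = False) -> Markers:
    """Derive marker flags from one clinical record (mapping or Series).

    ER/PR positive means IHC strictly greater than 10% staining; TNBC
    requires ER-, PR- and HER2-; node-positive means >= 1 positive node.
    Sub-micrometastases, when encoded as 0 nodes, stay node-negative
    unless ``submicro_is_positive`` (their registry handling is not
    standardized). NA inputs propagate to None flags.
    """
    er = _flag(record.get("er_ihc_pct"), lambda v: v > ER_PR_IHC_CUTOFF)
    pr = _flag(record.get("pr_ihc_pct"), lambda v: v > ER_PR_IHC_CUTOFF)
    her2 = _flag(record.get("her2"), lambda v: int(v) == 1)
    nodes = record.get("ln_pos_nodes")
    if pd.isna(nodes):
        ln = None
    else:
        ln = bool(nodes >= 1)
        if submicro_is_positive and record.get("ln_submicro", 0) == 1:
            ln = True
    if er is None or pr is None or her2 is None:
        tnbc = None
        if er is False and pr is False and her2 is False:
            tnbc = True  # unreachable guard; kept for clarity
    else:
        tnbc = (not er) and (not pr) and (not her2)
    return Markers(er_pos=er, pr_pos=pr, her2_pos=her2, tnbc=tnbc, ln_pos=ln)


def assign_assessment_group(record, submicro_is_positive: bool = False) -> AssessmentGroup:
    """Assign one record to its clinical assessment group.

    "Untreated" means all three adjuvant flags are 0 (only treatment was
    surgery). Mixed or unexpected regimens, and records with NA markers or
    NA treatment flags, fall to NONE.
    """
    m = derive_markers(record, submicro_is_positive=submicro_is_positive)
    flags = [record.get("treat_endo"), record.get("treat_act"),
             record.get("treat_antiher2")]
    if any(pd.isna(f) for f in flags):
        return AssessmentGroup.NONE
    endo, act, antiher2 = (int(f) for f in flags)
    untreated = not (endo or act or antiher2)

    if m.tnbc is True:
        if act and not endo and not antiher2:
            return AssessmentGroup.TNBC_ACT
        if untreated:
            return AssessmentGroup.TNBC_UNTREATED
        return AssessmentGroup.NONE

    if m.her2_pos is True and m.er_pos is not None:
        if not m.er_pos and antiher2 and act and not endo:
            return AssessmentGroup.HER2_ERNEG_HER2ACT
        if m.er_pos and antiher2 and act and endo:
            return AssessmentGroup.HER2_ERPOS_HER2ACT_ENDO
        return AssessmentGroup.NONE

    if m.er_pos is True and m.her2_pos is False and m.ln_pos is not None:
        if antiher2:
            return AssessmentGroup.NONE
        if not m.ln_pos:
            if endo and not act:
                return AssessmentGroup.ERPOS_LNNEG_ENDO
            if endo and act:
                return AssessmentGroup.ERPOS_LNNEG_ENDO_ACT
            if untreated:
                return AssessmentGroup.ERPOS_LNNEG_UNTREATED
        else:
            if endo and not act:
                return AssessmentGroup.ERPOS_LNPOS_ENDO
            if endo and act:
                return AssessmentGroup.ERPOS_LNPOS_ENDO_ACT
        return AssessmentGroup.NONE

    return AssessmentGroup.NONE


def add_assessment_groups(clinical: pd.DataFrame,
                          submicro_is_positive: bool = False) -> pd.DataFrame:
    """Return a copy of the clinical table with an ``assessment_group`` column."""
    out = clinical.copy()
    out["assessment_group"] = [
        assign_assessment_group(row, submicro_is_positive=submicro_is_positive).value
        for _, row in clinical.iterrows()
    ]
    return out


def proportions_by(labels: pd.DataFrame | pd.Series,
                   stratifier: pd.Series) -> pd.DataFrame:
    """Per-stratum class proportions for one or more label columns.

    Fractions are computed over non-NA labels within each stratum and sum
    to 1; the NA rate (NA labels / stratum size) is reported separately in
    the ``na_rate`` column. Empty strata are omitted with a log entry.

    Returns a tidy frame: stratum, signature, label, count, fraction, na_rate.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_frame(labels.name or "label")
    if len(labels) != len(stratifier):
        raise ValueError("labels and stratifier lengths differ")
    rows = []
    strat = np.asarray(stratifier)
    for stratum in pd.unique(strat):
        mask = strat == stratum
        if not mask.any():
            logger.info("proportions_by: empty stratum %r omitted", stratum)
            continue
        sub = labels.loc[mask]
        for col in labels.columns:
            vals = sub[col]
            non_na = vals.dropna()
            na_rate = 1.0 - len(non_na) / len(vals)
            counts = non_na.value_counts()
            for label, count in counts.items():
                rows.append({
                    "stratum": stratum, "signature": col, "label": label,
                    "count": int(count), "fraction": count / len(non_na),
                    "na_rate": na_rate,
                })
            if counts.empty:
                rows.append({"stratum": stratum, "signature": col, "label": np.nan,
                             "count": 0, "fraction": np.nan, "na_rate": na_rate})
    return pd.DataFrame(rows)
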