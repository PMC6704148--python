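"""Pairwise agreement between risk classifiers, agreement-chart geometry
and consensus risk voting.

The central statistic is *exact agreement*: the percentage of samples two
classifiers assign identical ordered risk classes (low < intermediate <
high). A second view omits every sample called intermediate by either
classifier, isolating low-vs-high disagreement. The agreement chart is a
Bangdiwala-style graphical contingency-table summary: marginal rectangles
from cumulative row/column totals, exact-agreement black squares sized by
the diagonal cells, and gray partial-agreement zones for one-level-off
cells. Consensus voting calls a sample low- or high-risk only when every
signature in a panel agrees.

NA handling is pairwise-complete: each comparison drops only the samples
missing in that pair, not listwise across all signatures (this changes
denominators and is therefore stated explicitly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RISK_ORDER = ["low", "intermediate", "high"]


@dataclass
class ContingencyTable:
    """Cross-tabulation of two paired ordered-label vectors."""

    row_classes: list[str]
    col_classes: list[str]
    counts: np.ndarray  # rows x cols, non-negative ints
    n: int
    n_excluded: int = 0  # pairs dropped for NA in either vector

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_classes), len(self.col_classes)):
            raise ValueError("counts shape does not match class lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.sum() != self.n:
            raise ValueError("n does not equal the sum of counts")


def contingency(labels_a, labels_b, class_order: list[str]) -> ContingencyTable:
    """Build the pairwise-complete contingency table (rows = a, cols = b)."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors must be paired (equal length)")
    keep = a.notna() & b.notna()
    n_excluded = int((~keep).sum())
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no pairwise-complete samples")
    bad = set(a) | set(b)
    bad -= set(class_order)
    if bad:
        raise ValueError(f"labels outside class_order: {sorted(bad)}")
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    np.add.at(counts, (a.map(idx).to_numpy(), b.map(idx).to_numpy()), 1)
    return ContingencyTable(list(class_order), list(class_order), counts,
                            n=int(len(a)), n_excluded=n_excluded)


def exact_agreement(table: ContingencyTable) -> float:
    """Percent of samples on the diagonal: 100 * trace / n."""
    if table.n < 1:
        raise ValueError("empty table")
    return 100.0 * float(np.trace(table.counts)) / table.n


def agreement_excluding_intermediate(labels_a, labels_b,
                                     intermediate: str = "intermediate",
                                     class_order: list[str] | None = None) -> float:
    """Exact agreement after omitting every sample called intermediate by
    either classifier. Returns NaN (with a log entry) when nothing remains."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors must be paired (equal length)")
    keep = a.notna() & b.notna() & (a != intermediate) & (b != intermediate)
    if not keep.any():
        logger.info("agreement_excluding_intermediate: no retained samples")
        return float("nan")
    order = class_order or [c for c in RISK_ORDER if c != intermediate]
    extra = (set(a[keep]) | set(b[keep])) - set(order)
    order = list(order) + sorted(extra)
    return exact_agreement(contingency(a[keep], b[keep], order))


def pairwise_agreement_matrix(calls: pd.DataFrame, signatures: list[str],
                              group_labels: pd.Series | None = None,
                              mode: str = "all_classes",
                              intermediate: str = "intermediate",
                              class_order: list[str] | None = None,
                              min_samples: int = 2):
    """Symmetric percent-agreement matrix per assessment group.

    ``mode='all_classes'`` uses exact agreement over all classes;
    ``'low_high_only'`` applies the intermediate-omission rule per pair
    (two-class signatures simply contribute all their samples). Returns
    ``(matrices, summaries)``: a dict group -> DataFrame (diagonal 100)
    and a tidy frame of off-diagonal distribution summaries.
    """
    if mode not in ("all_classes", "low_high_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    order = class_order or RISK_ORDER
    if group_labels is None:
        group_labels = pd.Series("all", index=calls.index)
    matrices: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for group in pd.unique(group_labels):
        sub = calls.loc[np.asarray(group_labels) == group, signatures]
        usable = sub.notna().any(axis=1).sum()
        if usable < min_samples:
            logger.info("pairwise_agreement_matrix: group %r skipped (<%d usable)",
                        group, min_samples)
            continue
        mat = pd.DataFrame(100.0, index=signatures, columns=signatures)
        for i, s1 in enumerate(signatures):
            for s2 in signatures[i + 1:]:
                try:
                    if mode == "all_classes":
                        val = exact_agreement(contingency(sub[s1], sub[s2], order))
                    else:
                        val = agreement_excluding_intermediate(
                            sub[s1], sub[s2], intermediate=intermediate)
                except ValueError:
                    val = float("nan")
                mat.loc[s1, s2] = mat.loc[s2, s1] = val
        matrices[group] = mat
        off = mat.to_numpy()[~np.eye(len(signatures), dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size:
            q1, med, q3 = np.percentile(off, [25, 50, 75])
            summary_rows.append({
                "group": group, "mode": mode, "n_pairs": len(off) // 2,
                "min": off.min(), "q1": q1, "median": med, "q3": q3,
                "max": off.max(),
            })
    return matrices, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# agreement-chart geometry


@dataclass
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float


@dataclass
class AgreementChartGeometry:
    """Coordinates (in counts, origin bottom-left, axes 0..n) of an
    agreement chart for a 2- or 3-class contingency table.

    x axis follows the column classifier's cumulative totals, y axis the
    row classifier's. For class k: the marginal rectangle spans the
    cumulative totals; the black square has side counts[k, k] and is
    offset inside the rectangle by the cumulative cell totals of the
    previous levels; the gray zone spans the within-one-level cells.
    """

    n: int
    classes: list[str]
    rectangles: list[Rect] = field(default_factory=list)
    black_squares: list[Rect] = field(default_factory=list)
    gray_zones: list[Rect] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def build_agreement_chart(table: ContingencyTable) -> AgreementChartGeometry:
    """Compute agreement-chart geometry from a contingency table.

    Degenerate tables (all mass in one class) yield zero-width rectangles
    and remain valid.
    """
    if table.row_classes != table.col_classes:
        raise ValueError("agreement chart needs identical ordered classes on both axes")
    k = len(table.row_classes)
    if k not in (2, 3):
        raise ValueError("agreement chart supports 2 or 3 ordered classes")
    counts = table.counts
    row_cum = np.concatenate([[0], np.cumsum(counts.sum(axis=1))])  # y axis
    col_cum = np.concatenate([[0], np.cumsum(counts.sum(axis=0))])  # x axis

    geom = AgreementChartGeometry(n=table.n, classes=list(table.row_classes))
    for i in range(k):
        geom.rectangles.append(Rect(
            x0=float(col_cum[i]), y0=float(row_cum[i]),
            x1=float(col_cum[i + 1]), y1=float(row_cum[i + 1])))
        # black square: side counts[i, i], offset by previous-level cell totals
        x_off = float(counts[:i, i].sum())   # samples of column class i with lower row class
        y_off = float(counts[i, :i].sum())   # samples of row class i with lower column class
        side = float(counts[i, i])
        geom.black_squares.append(Rect(
            x0=col_cum[i] + x_off, y0=row_cum[i] + y_off,
            x1=col_cum[i] + x_off + side, y1=row_cum[i] + y_off + side))
        # gray zone: spans cells within one level of i along both axes
        lo, hi = max(0, i - 1), min(k, i + 2)
        gx0 = float(counts[:lo, i].sum())
        gx1 = float(counts[:hi, i].sum())
        gy0 = float(counts[i, :lo].sum())
        gy1 = float(counts[i, :hi].sum())
        geom.gray_zones.append(Rect(
            x0=col_cum[i] + gx0, y0=row_cum[i] + gy0,
            x1=col_cum[i] + gx1, y1=row_cum[i] + gy1))
    return geom


# ---------------------------------------------------------------------------
# consensus voting


VOTE_UNANIMOUS_LOW = "unanimous_low"
VOTE_UNANIMOUS_HIGH = "unanimous_high"
VOTE_DISCORDANT = "discordant"


def consensus_vote(calls: pd.DataFrame, rp_signatures: list[str],
                   low: str = "low", high: str = "high") -> pd.Series:
    """Per-sample consensus vote over a panel of risk-prediction signatures.

    unanimous_low/high iff every participating signature's call equals
    that class; discordant otherwise; NaN whenever any participating call
    is missing.
    """
    if len(rp_signatures) < 2:
        raise ValueError("need at least 2 risk-prediction signatures")
    sub = calls[rp_signatures]

    def one(row):
        if row.isna().any():
            return np.nan
        vals = set(row)
        if vals == {low}:
            return VOTE_UNANIMOUS_LOW
        if vals == {high}:
            return VOTE_UNANIMOUS_HIGH
        return VOTE_DISCORDANT

    out = sub.apply(one, axis=1)
    out.name = "consensus_vote"
    return out


def consensus_summary(votes: pd.Series, group_labels: pd.Series) -> pd.DataFrame:
    """Vote-category fractions per assessment group (fractions of the
    non-NA voted samples; NA rate reported separately)."""
    rows = []
    strat = np.asarray(group_labels)
    for group in pd.unique(strat):
        v = votes[strat == group]
        non_na = v.dropna()
        total = len(v)
        for cat in (VOTE_UNANIMOUS_LOW, VOTE_UNANIMOUS_HIGH, VOTE_DISCORDANT):
            count = int((non_na == cat).sum())
            rows.append({
                "group": group, "vote": cat, "count": count,
                "fraction": count / len(non_na) if len(non_na) else np.nan,
                "na_rate": 1 - len(non_na) / total if total else np.nan,
            })
    return pd.DataFrame(rows)
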