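"""SVG renderings: agreement charts, forest plots, KM curves.

All numbers come from already-computed result objects; nothing is
re-estimated here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .concord import AgreementChartGeometry
from .survival import KMCurve


def agreement_chart_svg(geom: AgreementChartGeometry, path,
                        xlabel: str = "", ylabel: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    n = geom.n
    ax.plot([0, n], [0, n], color="0.7", lw=0.8, zorder=0)
    for rect in geom.rectangles:
        ax.add_patch(plt.Rectangle((rect.x0, rect.y0), rect.x1 - rect.x0,
                                   rect.y1 - rect.y0, fill=False, lw=1.0))
    for rect in geom.gray_zones:
        ax.add_patch(plt.Rectangle((rect.x0, rect.y0), rect.x1 - rect.x0,
                                   rect.y1 - rect.y0, color="0.75", zorder=1))
    for rect in geom.black_squares:
        ax.add_patch(plt.Rectangle((rect.x0, rect.y0), rect.x1 - rect.x0,
                                   rect.y1 - rect.y0, color="black", zorder=2))
    ax.set_xlim(0, n)
    ax.set_ylim(0, n)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def km_svg(curves: dict[str, KMCurve], path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.step(c.times, c.survival, where="post", label=f"{label} (n={c.n})")
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("years")
    ax.set_ylabel("overall survival")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def forest_svg(table, path, title: str = "") -> None:
    """Forest plot from a flat HR table (columns: signature, class, hr,
    ci_low, ci_high)."""
    rows = table.dropna(subset=["hr"]).reset_index(drop=True)
    if rows.empty:
        return
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(rows) + 1.2))
    y = np.arange(len(rows))[::-1]
    ax.errorbar(rows["hr"], y,
                xerr=[rows["hr"] - rows["ci_low"], rows["ci_high"] - rows["hr"]],
                fmt="s", color="black", ms=4, lw=1, capsize=2)
    ax.axvline(1.0, color="0.6", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(rows["signature"].astype(str) + ": " + rows["class"].astype(str),
                       fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
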