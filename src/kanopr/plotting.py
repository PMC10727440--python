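"""Quadrant matrix graph of the satisfaction coefficients."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kano import AttributeResult


def matrix_graph(
    results: Sequence[AttributeResult],
    split: float | tuple[float, float] = 0.5,
    title: str = "Kano satisfaction matrix",
    path: str | Path | None = None,
):
    """Scatter SI (y) against |DSI| (x) with quadrant guides.

    Attributes flagged as unplaceable (modal reverse/questionable or
    undefined coefficients) are omitted.  Returns the matplotlib figure;
    saves to ``path`` (SVG/PNG by extension) when given.
    """
    si_split, dsi_split = split if isinstance(split, tuple) else (split, split)
    fig, ax = plt.subplots(figsize=(6, 6))
    for res in results:
        if res.flagged:
            continue
        x, y = abs(res.coefficients.dsi), res.coefficients.si
        ax.scatter(x, y, color="tab:blue", zorder=3)
        ax.annotate(str(res.attribute.id), (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    ax.axvline(dsi_split, color="grey", linewidth=1)
    ax.axhline(si_split, color="grey", linewidth=1)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("|DSI| (worse)")
    ax.set_ylabel("SI (better)")
    ax.set_title(title)
    for label, (x, y) in {
        "Q1: top priority": (0.98, 0.98),
        "Q2: satisfaction lever": (0.02, 0.98),
        "Q3: low impact": (0.02, 0.02),
        "Q4: dissatisfaction risk": (0.98, 0.02),
    }.items():
        ax.text(x, y, label, ha="right" if x > 0.5 else "left",
                va="top" if y > 0.5 else "bottom", fontsize=8, color="grey")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
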