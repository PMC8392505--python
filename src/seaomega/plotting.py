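"""Small plotting helpers for the three standard views.

These are conveniences, not publication figures: a covariate-vs-LCn-3
bubble chart, a score histogram per guideline group, and a two-panel diet
contribution bar chart. All take an optional axes argument and return it.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .attribute_index import IndexScore
from .diet import RESIDUAL_LABEL, DietSummary
from .records import CountryRecord


def bubble_plot(records: Sequence[CountryRecord], x: str, y: str = "lcn3_mg_day",
                size: str = "price_rank", ax=None):
    """Scatter two country variables with marker area from a third."""
    ax = ax or plt.gca()
    pts = [(r.get(x), r.get(y), r.get(size)) for r in records
           if r.get(x) is not None and r.get(y) is not None]
    if not pts:
        raise ValueError(f"no complete ({x}, {y}) pairs to plot")
    xs, ys, ss = zip(*pts)
    sizes = [20.0 if s is None else 10.0 + float(s) for s in ss]
    ax.scatter(xs, ys, s=sizes, alpha=0.6, edgecolor="k", linewidth=0.3)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def index_histograms(scores: Sequence[IndexScore], axes=None):
    """One score histogram (0-4) per guideline group."""
    groups = sorted({s.fbdg_group for s in scores})
    if axes is None:
        _, axes = plt.subplots(1, len(groups), figsize=(3 * len(groups), 3),
                               sharey=True)
        axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groups):
        vals = [s.score for s in scores if s.fbdg_group == g]
        ax.hist(vals, bins=np.arange(-0.5, 5.5), rwidth=0.85)
        ax.set_title(g)
        ax.set_xlabel("positive attributes")
    axes[0].set_ylabel("countries")
    return axes


def diet_bars(summary: DietSummary, ax=None):
    """Consumption vs LCn-3 share per item, observed profile."""
    ax = ax or plt.gca()
    names = list(summary.per_species) + [RESIDUAL_LABEL]
    cons = [summary.contribution(n).share_of_consumption * 100 for n in names]
    lcn3 = [summary.contribution(n).share_of_lcn3 * 100 for n in names]
    pos = np.arange(len(names))
    ax.bar(pos - 0.2, cons, width=0.4, label="% of consumption")
    ax.bar(pos + 0.2, lcn3, width=0.4, label="% of LCn-3")
    ax.set_xticks(pos, names, rotation=60, ha="right")
    ax.legend()
    return ax
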