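"""Figure helpers (Agg backend; figures are returned, callers save them)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterTree
from .validation import GHSASummary


def ratio_heatmap(matrix: pd.DataFrame, title: str) -> plt.Figure:
    """Context x protein heatmap of bounded ratios (diverging scale)."""
    fig, ax = plt.subplots(
        figsize=(max(6, 0.45 * matrix.shape[1]), max(2.5, 0.45 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized release difference")
    return fig


def ghsa_boxplot(summaries: Sequence[GHSASummary], title: str) -> plt.Figure:
    """Five-number box plot per combination (whiskers = min/max)."""
    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 2, 4))
    stats = []
    for s in summaries:
        lo, q1, med, q3, hi = s.five_numbers
        stats.append(
            {
                "label": s.combination.label,
                "whislo": lo,
                "q1": q1,
                "med": med,
                "q3": q3,
                "whishi": hi,
                "fliers": [],
            }
        )
    ax.bxp(stats, showfliers=False)
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_ylabel("GHSA index")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(title)
    return fig


def centroid_plot(tree: ClusterTree, need: np.ndarray | None, title: str) -> plt.Figure:
    """Centroid lines per (sub-)cluster over the protein axis, plus the
    total therapeutic need as a gray reference line."""
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(tree.proteins)), 4))
    x = np.arange(len(tree.proteins))
    if need is not None:
        ax.plot(x, need, color="gray", lw=2, label="therapeutic need")
    colors = plt.cm.tab10.colors
    for i, c in enumerate(sorted(tree.clusters, key=lambda c: c.members)):
        label = "{" + ",".join(c.members) + "}"
        ax.plot(x, c.centroid, color=colors[i % 10], lw=2, label=label)
        if c.subclusters is not None:
            for j, s in enumerate(sorted(c.subclusters, key=lambda s: s.members)):
                sub = "{" + ",".join(s.members) + "}"
                ax.plot(
                    x, s.centroid, color=colors[i % 10], lw=1.2,
                    ls=(0, (2, 2)) if j % 2 == 0 else (0, (4, 2)), label=sub,
                )
    ax.axhline(0.0, color="black", lw=0.6)
    ax.set_xticks(x, tree.proteins, rotation=90, fontsize=7)
    ax.set_ylabel("restoration capacity")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(title)
    ax.legend(fontsize=7)
    return fig


def partition_histogram(freq: pd.DataFrame, title: str, top: int = 10) -> plt.Figure:
    """Frequency (%) of the most common level-1 partitions."""
    head = freq.head(top)
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(head) + 2))
    ax.barh(range(len(head)), head["percent"], color="steelblue")
    ax.set_yticks(range(len(head)), head["partition"], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("frequency (%)")
    ax.set_title(title)
    return fig
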