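"""Muller-style stacked-area plot of lineage dynamics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .freq_inference import FrequencyEstimate


def muller_plot(estimates: list[FrequencyEstimate], path: str | None = None, ax=None):
    """Stacked exclusive frequencies over time; white space above the
    stack is the residual (diversity not represented by any lineage)."""
    if not estimates:
        raise ValueError("no estimates to plot")
    estimates = sorted(estimates, key=lambda e: e.timepoint)
    lineages = sorted(estimates[0].inclusive.keys())
    t = [e.timepoint for e in estimates]
    excl = np.array([[e.exclusive()[l] for l in lineages] for e in estimates])
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(t, excl.T, labels=lineages)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("exclusive lineage frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small", ncol=2, loc="upper right")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def muller_plot_from_table(df, path: str | None = None, ax=None):
    """Same plot from a written frequency table (timepoint, lineage,
    exclusive_freq columns), tolerant of 6-decimal rounding."""
    wide = df.pivot(index="timepoint", columns="lineage", values="exclusive_freq")
    wide = wide.sort_index()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(wide.index, wide.to_numpy().T.clip(min=0), labels=list(wide.columns))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("exclusive lineage frequency")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small", ncol=2, loc="upper right")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
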