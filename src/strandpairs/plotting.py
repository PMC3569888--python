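"""Plots of the ratio distributions and cumulative curves."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from strandpairs.pair_stats import DatasetSummary, RATIO_VARIABLES


def plot_distribution(summary: DatasetSummary, ax=None):
    """Grouped bar chart of the R, Rt1, Rt2 histograms (percent per bin)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    n_vars = len(RATIO_VARIABLES)
    for k, var in enumerate(RATIO_VARIABLES):
        hist = summary.histograms[var]
        width = (hist["bin_high"] - hist["bin_low"]).iloc[0] / (n_vars + 1)
        ax.bar(
            hist["bin_low"] + (k + 0.5) * width,
            hist["percent"],
            width=width,
            label=var,
        )
    ax.set_xlabel("ratio (%)")
    ax.set_ylabel("percent of pairs")
    ax.legend()
    return ax


def plot_cumulative(summary: DatasetSummary, ax=None):
    """Cumulative percent CP(x) of R, Rt1, Rt2 against the ratio grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for var in RATIO_VARIABLES:
        xs, cps = zip(*summary.cumulative[var])
        ax.plot(xs, cps, marker="o", label=var)
    ax.set_xlabel("ratio (%)")
    ax.set_ylabel("cumulative percent of pairs")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax


def save_summary_plots(summary: DatasetSummary, out_dir) -> list:
    from pathlib import Path

    out = Path(out_dir)
    paths = []
    for name, fn in (("distribution", plot_distribution), ("cumulative", plot_cumulative)):
        ax = fn(summary)
        path = out / f"{name}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        paths.append(path)
    return paths
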