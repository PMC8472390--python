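"""Minimal static plotting helpers for run tables and summaries.

These are convenience views of the tidy exports (run tracks per individual,
length-class bars, chromosome-coverage heatmap); the exports themselves are
the primary interface for downstream visualization tools.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .summarize import LENGTH_CLASS_LABELS, PopulationSummary


def plot_run_track(run_frame: pd.DataFrame, chromosome: str, ax=None):
    """One horizontal segment per run; rows are individuals."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sub = run_frame[run_frame["chromosome"].astype(str) == str(chromosome)]
    individuals = {iid: k for k, iid in enumerate(sorted(sub["individual"].unique()))}
    for row in sub.itertuples(index=False):
        y = individuals[row.individual]
        ax.hlines(y, row.start_bp / 1e6, row.end_bp / 1e6, linewidth=2)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("individual")
    ax.set_title(f"runs on chromosome {chromosome}")
    return ax


def plot_length_class_bars(summaries: Sequence[PopulationSummary], ax=None):
    """Mean run count per length class, grouped by population."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    width = 0.8 / max(1, len(summaries))
    for k, s in enumerate(summaries):
        xs = [i + k * width for i in range(len(LENGTH_CLASS_LABELS))]
        ys = [s.class_mean_count.get(lab, 0.0) for lab in LENGTH_CLASS_LABELS]
        ax.bar(xs, ys, width=width, label=s.population_label)
    ax.set_xticks(range(len(LENGTH_CLASS_LABELS)))
    ax.set_xticklabels(LENGTH_CLASS_LABELS)
    ax.set_xlabel("length class (Mb)")
    ax.set_ylabel("mean runs per individual")
    ax.legend(fontsize="small")
    return ax


def plot_coverage_heatmap(coverage_frame: pd.DataFrame, ax=None):
    """Population x chromosome run-coverage matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    pivot = coverage_frame.pivot(index="population", columns="chromosome", values="coverage")
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis", vmin=0)
    ax.set_xticks(range(len(pivot.columns)))
    ax.set_xticklabels(pivot.columns, fontsize="small")
    ax.set_yticks(range(len(pivot.index)))
    ax.set_yticklabels(pivot.index, fontsize="small")
    plt.colorbar(im, ax=ax, label="fraction of chromosome in runs")
    return ax
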