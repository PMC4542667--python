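"""Minimal figures: clone-tracking line plot and subset stacked bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .subsets import SubsetDistribution
from .tracking import TrackingMatrix


def plot_tracking(matrix: TrackingMatrix, ax=None):
    """Timepoint-vs-frequency line plot, one line per persistent clone."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cols = list(matrix.frequencies.columns)
    for key in matrix.persistent_keys:
        ys = [matrix.frequencies.at[key, c] for c in cols]
        ax.plot(range(len(cols)), ys, marker="o",
                label=matrix.clone_ids.get(key, str(key)))
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("clone frequency")
    ax.set_title(f"Persistent clones, {matrix.subject_id}")
    if matrix.persistent_keys:
        ax.legend(fontsize=7)
    return ax


def plot_subset_distribution(dist: SubsetDistribution, ax=None, normalized=True):
    """Stacked single-bar plot of a clone's corrected subset distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    entries = dist.shares if (normalized and dist.shares) else dist.contributions
    bottom = 0.0
    for subset in sorted(entries):
        ax.bar([0], [entries[subset]], bottom=bottom, label=subset)
        bottom += entries[subset]
    ax.set_xticks([])
    ax.set_ylabel("share" if normalized else "fraction of CD4+ cells")
    ax.set_title(dist.label, fontsize=8)
    ax.legend(fontsize=7)
    return ax
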