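"""Figures mirroring the published layouts: per-cluster mean curves with
SD bands, per-cluster spaghetti plots, and observed/censored counts per
timepoint.  No attempt at pixel fidelity."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_cluster_means", "plot_spaghetti", "plot_missingness"]

_COLORS = ["#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#8c564b", "#e377c2"]


def plot_cluster_means(matrix, labels, ax=None):
    """Mean observed cortisol per cluster per timepoint, ± 1 SD."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hours = np.asarray(matrix.col_hours, dtype=float)
    values, mask = matrix.values, matrix.mask
    for i, g in enumerate(np.unique(labels)):
        rows = np.asarray(labels) == g
        means = np.array([values[rows & mask[:, j], j].mean()
                          if (rows & mask[:, j]).any() else np.nan
                          for j in range(hours.size)])
        sds = np.array([values[rows & mask[:, j], j].std(ddof=1)
                        if (rows & mask[:, j]).sum() > 1 else 0.0
                        for j in range(hours.size)])
        c = _COLORS[i % len(_COLORS)]
        ax.plot(hours, means, "-o", color=c, label=f"cluster {g}")
        ax.fill_between(hours, means - sds, means + sds, color=c, alpha=0.15)
    ax.set_xlabel("hours post-op")
    ax.set_ylabel("serum cortisol (mcg/dL)")
    ax.legend()
    return ax


def plot_spaghetti(matrix, labels, axes=None):
    """Individual observed trajectories, one panel per cluster."""
    groups = np.unique(labels)
    if axes is None:
        _, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3.5),
                               sharey=True)
        axes = np.atleast_1d(axes)
    hours = np.asarray(matrix.col_hours, dtype=float)
    for ax, g in zip(axes, groups):
        for i in np.flatnonzero(np.asarray(labels) == g):
            obs = matrix.mask[i]
            if obs.sum() < 2:
                continue  # single-timepoint patients cluster but are not drawn
            ax.plot(hours[obs], matrix.values[i, obs], "-", alpha=0.5,
                    color=_COLORS[list(groups).index(g) % len(_COLORS)])
        ax.set_title(f"cluster {g}")
        ax.set_xlabel("hours post-op")
    axes[0].set_ylabel("serum cortisol (mcg/dL)")
    return axes


def plot_missingness(matrix, steroid_times=None, ax=None):
    """Observed vs censored/missing patient counts per timepoint."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    hours = np.asarray(matrix.col_hours, dtype=float)
    n = matrix.shape[0]
    observed = matrix.mask.sum(axis=0)
    censored = np.zeros_like(observed)
    if steroid_times is not None:
        st = np.array([np.inf if t is None else t for t in steroid_times])
        censored = (st[:, None] < hours[None, :]).sum(axis=0)
    other = n - observed - censored
    ax.bar(hours, observed, width=4, label="observed", color="#2ca02c")
    ax.bar(hours, censored, width=4, bottom=observed, label="post-steroid",
           color="#d62728")
    ax.bar(hours, other, width=4, bottom=observed + censored,
           label="otherwise missing", color="#ff7f0e")
    ax.set_xlabel("hours post-op")
    ax.set_ylabel("patients")
    ax.legend()
    return ax
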