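"""Figures for the pipeline outputs (heatmaps, cluster means, histograms, scatters)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def profile_heatmap(normalized: pd.DataFrame, assignments: pd.Series, path: str) -> None:
    """Max-normalized profiles sorted by cluster, one heatmap panel per run."""
    order = assignments.sort_values(kind="stable").index
    data = normalized.loc[order].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("timepoint")
    ax.set_ylabel("transcripts (grouped by cluster)")
    bounds = np.cumsum(assignments.value_counts().sort_index().values)[:-1]
    for b in bounds:
        ax.axhline(b - 0.5, color="w", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_mean_plot(cluster_means: pd.DataFrame, times, path: str) -> None:
    k = len(cluster_means)
    fig, axes = plt.subplots(int(np.ceil(k / 2)), 2, figsize=(8, 1.6 * k / 2 + 2),
                             sharex=True, sharey=True)
    for ax, (label, row) in zip(np.ravel(axes), cluster_means.iterrows()):
        ax.plot(times, row.values, color="tab:blue")
        ax.set_title(f"cluster {label}", fontsize=9)
    for ax in np.ravel(axes)[k:]:
        ax.set_visible(False)
    fig.supxlabel("hours post-fertilization")
    fig.supylabel("mean normalized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_histograms(neighbor_r, random_r, path: str, opposing_r=None) -> None:
    """Overlaid correlation distributions: neighbor vs random (and opposing-strand)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(-1, 1, 41)
    ax.hist(neighbor_r, bins=bins, alpha=0.55, density=True, label="lncRNA–neighbor", color="tab:blue")
    ax.hist(random_r, bins=bins, alpha=0.55, density=True, label="lncRNA–random", color="tab:green")
    if opposing_r is not None and len(opposing_r):
        ax.hist(opposing_r, bins=bins, histtype="step", density=True, lw=1.5,
                label="antisense neighbor", color="tab:cyan")
    ax.set_xlabel("Pearson correlation")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def spatial_scatter(counts: pd.DataFrame, regions: pd.Series, enriched: pd.Series,
                    condition_a: str, condition_b: str, path: str) -> None:
    """Mean log2 expression in condition B vs A, enriched transcripts highlighted."""
    a_cols = regions.index[regions == condition_a]
    b_cols = regions.index[regions == condition_b]
    x = np.log2(counts[a_cols].mean(axis=1) + 1)
    y = np.log2(counts[b_cols].mean(axis=1) + 1)
    hot = enriched != "none"
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x[~hot], y[~hot], s=6, alpha=0.4, color="gray")
    ax.scatter(x[hot], y[hot], s=12, alpha=0.9, color="crimson",
               label=f"enriched (n={int(hot.sum())})")
    lim = max(x.max(), y.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="k", lw=0.8)
    ax.set_xlabel(f"log2 mean counts, {condition_a}")
    ax.set_ylabel(f"log2 mean counts, {condition_b}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def gp_profile_plot(fit, path: str, raw_values=None) -> None:
    """Posterior mean with predictive 95% band for one transcript."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(fit.times, fit.posterior_lower95, fit.posterior_upper95,
                    alpha=0.25, color="tab:blue", label="95% predictive band")
    ax.plot(fit.times, fit.posterior_mean, color="tab:blue", label="GP posterior mean")
    if raw_values is not None:
        ax.plot(fit.times, raw_values, ".", ms=3, color="k", alpha=0.6, label="observed")
    ax.set_xlabel("hours post-fertilization")
    ax.set_ylabel("log2(RPKM+1)")
    ax.set_title(f"{fit.transcript_id} (SNR={fit.snr:.2f})", fontsize=10)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
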