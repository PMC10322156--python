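"""Diagnostic plots for ABC runs (SVG/PNG via matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .abc_infer import PosteriorEstimate, PriorCheckResult, ReferenceTable

__all__ = ["plot_prior_check", "plot_posteriors"]


def plot_prior_check(result: PriorCheckResult, path) -> None:
    """Observed statistics vector over the simulated cloud in the first
    two principal components, with the goodness-of-fit null."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(result.pca_table[:, 0], result.pca_table[:, 1], s=4,
                alpha=0.3, label="simulated")
    ax1.scatter(*result.pca_observed, color="red", marker="*", s=150,
                label="observed")
    ax1.set_xlabel("PC1")
    ax1.set_ylabel("PC2")
    ax1.legend(frameon=False)
    ax2.hist(result.gof_null, bins=30, alpha=0.7)
    ax2.axvline(result.gof_observed, color="red")
    ax2.set_xlabel("goodness-of-fit statistic")
    ax2.set_title(f"p = {result.p_value:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_posteriors(estimate: PosteriorEstimate, table: ReferenceTable,
                    path) -> None:
    """Adjusted posterior densities against the table (≈ prior) per
    parameter."""
    names = list(estimate.samples.columns)
    ncol = min(4, len(names))
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), names):
        prior_vals = table.data[name].dropna().to_numpy(dtype=float)
        ax.hist(prior_vals, bins=25, density=True, alpha=0.4, label="prior")
        ax.hist(estimate.samples[name], bins=25, density=True, alpha=0.6,
                label="posterior")
        ax.axvline(estimate.medians[name], color="black", lw=1)
        ax.set_title(name, fontsize=8)
    for ax in axes.ravel()[len(names):]:
        ax.axis("off")
    axes[0, 0].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
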