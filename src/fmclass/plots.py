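"""Diagnostic plots: gap curve and PCA class scatter.

Matplotlib is imported lazily so headless analysis runs never touch it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cluster import GapStatisticResult, PCAProjection


def plot_gap_curve(gap: GapStatisticResult, path: str | Path) -> None:
    """Gap value per k with reference standard errors and the chosen k."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(gap.k_values, gap.gap, yerr=gap.s, fmt="o-", capsize=3)
    ax.axvline(gap.chosen_k, color="crimson", ls="--", lw=1,
               label=f"chosen k = {gap.chosen_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("gap statistic")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_classes(pca: PCAProjection, labels, names: dict[int, str],
                     path: str | Path) -> None:
    """Tags on the first two principal components, coloured by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cluster in sorted(set(labels)):
        mask = labels == cluster
        ax.scatter(pca.coords[mask, 0], pca.coords[mask, 1], s=12,
                   label=names.get(cluster, str(cluster)), alpha=0.7)
    ax.set_xlabel(f"PC1 ({pca.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.percent_variance[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
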