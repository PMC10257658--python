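"""Basic renderers for the cohort heatmap and group boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import HeterogeneityMatrix  # noqa: E402

__all__ = ["plot_heterogeneity_heatmap", "plot_group_boxplot"]


def plot_heterogeneity_heatmap(
    matrix: HeterogeneityMatrix, clustering: dict, path
) -> None:
    """Heatmap of percent common variants, rows/columns in dendrogram
    leaf order."""
    order = clustering["order"]
    idx = [matrix.samples.index(s) for s in order]
    m = matrix.matrix[idx][:, idx]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(m, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=4)
    ax.set_yticklabels(order, fontsize=4)
    fig.colorbar(im, ax=ax, label="% common variants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_boxplot(per_sample, path, features=("SNV", "indel", "total")) -> None:
    """Boxplots of per-sample variant counts split by group."""
    groups = sorted(per_sample["group"].unique())
    fig, axes = plt.subplots(1, len(features), figsize=(4 * len(features), 4))
    if len(features) == 1:
        axes = [axes]
    for ax, feat in zip(axes, features):
        data = [per_sample.loc[per_sample["group"] == g, feat] for g in groups]
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(feat)
        ax.set_ylabel("variants per sample")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
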