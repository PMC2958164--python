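"""QC and summary figures (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import ExpressionMatrix


def plot_normalization_boxplots(before: ExpressionMatrix, after: ExpressionMatrix, path) -> None:
    """Side-by-side per-sample intensity box-plots, pre- vs post-normalization.

    Intensities are shown on log10 scale (zeros dropped) so the whole
    dynamic range is visible.
    """
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, m, title in ((axes[0], before, "pre-normalization"), (axes[1], after, "normalized")):
        data = [
            np.log10(col[col > 0]) for _, col in m.intensities.items()
        ]
        ax.boxplot(data, tick_labels=m.sample_ids, showfliers=False)
        ax.set_title(title)
        ax.tick_params(axis="x", rotation=90)
    axes[0].set_ylabel("log10 intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_enrichment_comparison(matrix: pd.DataFrame, path) -> None:
    """Grouped bar chart of -log10 p per pathway across contrasts."""
    n_path, n_contrast = matrix.shape
    x = np.arange(n_path)
    width = 0.8 / max(n_contrast, 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * n_path), 4))
    for j, contrast in enumerate(matrix.columns):
        ax.bar(x + j * width, matrix[contrast], width=width, label=contrast)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(matrix.index, rotation=90, fontsize=7)
    ax.set_ylabel("-log10 p")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
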