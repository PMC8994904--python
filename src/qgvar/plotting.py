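"""Optional figures: component trajectories and LD heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decomposition import COMPONENTS

__all__ = ["plot_trajectory", "plot_ld_heatmap"]


def plot_trajectory(components: pd.DataFrame, path: str | None = None):
    """Line plot of the six component variances along generations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in COMPONENTS:
        ax.plot(components["generation"], components[f"sigma2_{c}"], label=c)
    ax.set_xlabel("generation")
    ax.set_ylabel("variance (trait units$^2$)")
    ax.legend(frameon=False, ncol=3)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ld_heatmap(ld_table: pd.DataFrame, column: str = "r2_0",
                    path: str | None = None):
    """Heatmap of a pairwise LD metric from an ld_decay_summary table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(set(ld_table["gene_i"]) | set(ld_table["gene_j"]))
    idx = {g: k for k, g in enumerate(genes)}
    mat = np.full((len(genes), len(genes)), np.nan)
    for _, row in ld_table.iterrows():
        i, j = idx[row["gene_i"]], idx[row["gene_j"]]
        mat[i, j] = mat[j, i] = row[column]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(mat, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, label=column)
    ax.set_xlabel("gene")
    ax.set_ylabel("gene")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
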