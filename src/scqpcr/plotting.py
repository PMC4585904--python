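"""Figure helpers: expression heatmap, PCA scatter, lineage-score map."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import ExpressionMatrix, FateCalls, PCAResult
from .stage_dynamics import center_genes


def heatmap(expr: ExpressionMatrix, branches: pd.Series | None = None,
            path=None, ax=None):
    """Centred-expression heatmap, optionally ordered by branch."""
    centered = center_genes(expr).values
    if branches is not None:
        order = branches.sort_values(kind="stable").index
        centered = centered.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    vmax = np.nanpercentile(np.abs(centered.to_numpy()), 99)
    im = ax.imshow(centered.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("samples")
    ax.set_ylabel("genes")
    plt.colorbar(im, ax=ax, label="centred log2 expression")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def pca_scatter(result: PCAResult, sample_meta: pd.DataFrame, path=None, ax=None):
    """PC1/PC2 scatter coloured by developmental stage."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    stages = sample_meta.loc[result.scores.index, "stage"]
    for stage in stages.unique():
        pts = result.scores.loc[stages == stage]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=18, label=stage)
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.legend(fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def lineage_scatter(result: PCAResult, fates: FateCalls, path=None, ax=None):
    """Blastomere PC1/PC2 scatter coloured by lineage score."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cells = result.scores.index
    sc = ax.scatter(result.scores.iloc[:, 0], result.scores.iloc[:, 1],
                    c=fates.score.loc[cells], cmap="coolwarm", s=22)
    plt.colorbar(sc, ax=ax, label="lineage score (log2)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
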