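"""Figure rendering for score distributions and expression heatmaps.

All figures are derived from the numeric objects in :mod:`benchmark`; tests
and comparisons are made on those numeric exports, never on image bytes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .benchmark import HeatmapData, KDEResult
from .io import CATEGORIES

CATEGORY_COLORS = {
    "Metabolism": "goldenrod",
    "Development": "forestgreen",
    "Light Response": "royalblue",
}


def plot_kde(result: KDEResult, path: str | Path, title: str = "") -> None:
    """Density curve with a rug of the raw scores along the x axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.grid, result.density, color="steelblue")
    ax.fill_between(result.grid, result.density, alpha=0.25, color="steelblue")
    ax.plot(
        result.rug,
        np.zeros_like(result.rug),
        "|",
        color="black",
        markersize=12,
        alpha=0.6,
    )
    ax.set_xlabel("entropy score (bits)")
    ax.set_ylabel("probability density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(
    data: HeatmapData,
    path: str | Path,
    title: str = "",
    cmap: str = "viridis",
    score_cmap: str = "BrBG",
    show_gene_names: bool = False,
) -> None:
    """Entropy-ranked log2-TPM heatmap.

    Score sidebar on the left (low at the top), category color bar on top,
    optional gene names on the right.
    """
    mat = data.matrix.to_numpy()
    n_genes, n_cond = mat.shape
    fig = plt.figure(figsize=(10, max(3.0, min(10.0, 0.1 * n_genes + 2))))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[0.03, 1], height_ratios=[0.04, 1], hspace=0.02, wspace=0.02
    )
    ax_cat = fig.add_subplot(gs[0, 1])
    ax_score = fig.add_subplot(gs[1, 0])
    ax_main = fig.add_subplot(gs[1, 1])

    im = ax_main.imshow(mat, aspect="auto", cmap=cmap, interpolation="nearest")
    ax_main.set_xticks([])
    ax_main.set_yticks([])
    if show_gene_names and n_genes <= 60:
        ax_main.yaxis.tick_right()
        ax_main.set_yticks(range(n_genes))
        ax_main.set_yticklabels(data.matrix.index, fontsize=6)

    ax_score.imshow(
        data.row_scores[:, None], aspect="auto", cmap=score_cmap, interpolation="nearest"
    )
    ax_score.set_xticks([])
    ax_score.set_yticks([])
    ax_score.set_ylabel("entropy (low → high)")

    cat_idx = np.array(
        [[CATEGORIES.index(c) for c in data.column_categories]], dtype=float
    )
    cat_cmap = matplotlib.colors.ListedColormap(
        [CATEGORY_COLORS[c] for c in CATEGORIES]
    )
    ax_cat.imshow(
        cat_idx, aspect="auto", cmap=cat_cmap, interpolation="nearest", vmin=0, vmax=2
    )
    ax_cat.set_xticks([])
    ax_cat.set_yticks([])
    if title:
        ax_cat.set_title(title)
    fig.colorbar(im, ax=ax_main, fraction=0.03, pad=0.08, label="log2(TPM + pc)")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_score_histogram(
    scores, path: str | Path, bin_width: float = 0.25, title: str = ""
) -> np.ndarray:
    """Histogram of all scores; returns the bin counts (they sum to the
    scored-gene total)."""
    x = np.asarray(scores, dtype=float)
    edges = np.arange(0.0, x.max() + bin_width, bin_width)
    if edges[-1] <= x.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(x, bins=edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=bin_width, align="edge", color="slategray")
    ax.set_xlabel("entropy score (bits)")
    ax.set_ylabel("genes")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return counts
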