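"""Benchmarking entropy scores against labeled gene sets.

Published gene sets expected to be constitutively expressed (housekeeping,
transcription/translation machinery) should concentrate at low scores, while
induced sets (light response, sexual development) should shift toward high
scores. This module extracts a set's scores, estimates their density
(Gaussian KDE with rug), builds entropy-ranked log2-TPM heatmap matrices, and
selects the extreme-scoring genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .exceptions import DegenerateDistributionError, EmptyBenchmarkError
from .io import ConditionTable, GeneSet
from .metric import CLASS_EXCLUDED, EntropyTable, TPMMatrix

KDE_GRID_POINTS = 512


@dataclass
class GeneSetScores:
    """Defined scores for a gene set, plus the IDs that could not be scored."""

    name: str
    gene_ids: list[str]  # scored members, table order preserved
    scores: np.ndarray
    missing: list[str]  # absent from the entropy table
    excluded: list[str]  # present but with undefined score


@dataclass
class KDEResult:
    """Gaussian kernel density of a score list on a fixed grid.

    The grid spans [min - 3*bandwidth, max + 3*bandwidth] so the trapezoidal
    integral of ``density`` is ~1; ``rug`` carries the raw scores.
    """

    grid: np.ndarray
    density: np.ndarray
    rug: np.ndarray
    bandwidth: float

    @property
    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class HeatmapData:
    """log2(TPM + pseudocount) matrix with rows ranked by entropy score.

    Rows ascend by score (ties broken by gene ID); ``row_scores`` carries the
    scores in row order and ``column_categories`` the condition categories.
    """

    matrix: pd.DataFrame
    row_scores: np.ndarray
    column_categories: list[str]
    pseudocount: float

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "entropy", self.row_scores)
        header = "\t".join(["category", ""] + self.column_categories)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            out.to_csv(fh, sep="\t", index_label="gene_id")


def geneset_scores(table: EntropyTable, gs: GeneSet) -> GeneSetScores:
    """Pull a gene set's defined scores out of an entropy table.

    IDs absent from the table and IDs with undefined (excluded) scores are
    returned separately, never silently dropped.
    """
    index = table.frame.index
    members = set(gs.gene_ids)
    missing = [g for g in gs.gene_ids if g not in index]
    present = table.frame.loc[index.isin(members)]
    excluded = list(present.index[present["class"] == CLASS_EXCLUDED])
    scored = present[present["class"] != CLASS_EXCLUDED]
    if scored.empty:
        raise EmptyBenchmarkError(f"gene set {gs.name!r} has no scored members")
    return GeneSetScores(
        name=gs.name,
        gene_ids=list(scored.index),
        scores=scored["entropy"].to_numpy(),
        missing=missing,
        excluded=excluded,
    )


def kde(scores, bandwidth_rule: str | float = "scott") -> KDEResult:
    """Gaussian kernel density estimate on a 512-point grid.

    ``bandwidth_rule`` is "scott", "silverman" or a fixed positive bandwidth
    in bits. Needs at least two scores with nonzero variance; constant scores
    raise :class:`DegenerateDistributionError` (plot a rug instead).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("KDE needs at least two scores")
    std = x.std(ddof=1)
    if std == 0:
        raise DegenerateDistributionError(
            "all scores identical; density undefined — use a rug-only plot"
        )
    if isinstance(bandwidth_rule, str):
        estimator = gaussian_kde(x, bw_method=bandwidth_rule)
        bw = float(estimator.factor * std)
    else:
        bw = float(bandwidth_rule)
        if bw <= 0:
            raise ValueError("fixed bandwidth must be positive")
        estimator = gaussian_kde(x, bw_method=bw / std)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, KDE_GRID_POINTS)
    return KDEResult(grid=grid, density=estimator(grid), rug=x, bandwidth=bw)


def _ranked_ids(frame: pd.DataFrame) -> pd.DataFrame:
    """Scored genes sorted ascending by score, ties by gene ID."""
    scored = frame[frame["class"] != CLASS_EXCLUDED]
    order = sorted(scored.index, key=lambda g: (scored.at[g, "entropy"], g))
    return scored.loc[order]


def ranked_heatmap(
    tpm: TPMMatrix,
    table: EntropyTable,
    gs: GeneSet,
    ct: ConditionTable,
    pseudocount: float = 1.0,
) -> HeatmapData:
    """Entropy-ranked log2-TPM heatmap matrix for a gene set.

    Rows are the set's scored genes sorted by score ascending (low at the
    top, as in a ranked heatmap), values are log2(TPM + pseudocount), and
    columns carry the condition categories. Excluded genes are omitted.
    """
    hits = geneset_scores(table, gs)  # raises EmptyBenchmarkError when none scored
    sub = table.frame.loc[hits.gene_ids]
    ranked = _ranked_ids(sub)
    mat = np.log2(tpm.values.loc[ranked.index].to_numpy(dtype=float) + pseudocount)
    matrix = pd.DataFrame(mat, index=ranked.index, columns=tpm.values.columns)
    return HeatmapData(
        matrix=matrix,
        row_scores=ranked["entropy"].to_numpy(),
        column_categories=ct.categories(tpm.condition_ids),
        pseudocount=pseudocount,
    )


def extreme_genes(table: EntropyTable, k: int = 100) -> tuple[list[str], list[str]]:
    """IDs of the k lowest- and k highest-scoring genes (disjoint lists).

    Ties are broken by gene ID; excluded genes are never selected. Raises
    ValueError when fewer than 2k genes are scored.
    """
    if k < 1:
        raise ValueError("k must be positive")
    ranked = _ranked_ids(table.frame)
    if len(ranked) < 2 * k:
        raise ValueError(f"need at least {2 * k} scored genes, have {len(ranked)}")
    ids = list(ranked.index)
    return ids[:k], ids[-k:]
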