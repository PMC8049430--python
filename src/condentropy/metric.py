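"""TPM normalization and the entropy-based condition-specificity score.

The score of a gene with cross-condition TPM fractions ``p`` over ``N``
conditions is

    S = sum_t p_t * log2(p_t * N) = log2(N) - H(p)      [bits]

with the convention 0*log2(0) = 0. S ranges from 0 (uniform expression,
constitutive) to log2(N) (all expression in one condition). A gene with zero
TPM in every condition has no fraction profile; its score is undefined and
the gene is classified ``excluded``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

CLASS_CONSTITUTIVE = "constitutive-like"
CLASS_SPECIFIC = "condition-specific"
CLASS_EXCLUDED = "excluded"

DEFAULT_THRESHOLD = 1.0  # bits; scores strictly above are condition-specific


@dataclass
class TPMMatrix:
    """Genes x conditions transcripts-per-million values.

    Every condition column with at least one nonzero count sums to 1e6;
    columns counted from zero reads everywhere are all-zero.
    """

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class FractionProfile:
    """One gene's TPM fractions across N conditions; ``p`` is None when the
    gene has zero TPM everywhere (undefined profile)."""

    p: np.ndarray | None
    n: int

    @property
    def defined(self) -> bool:
        return self.p is not None


@dataclass
class EntropyTable:
    """Per-gene specificity scores and class labels.

    ``frame`` is indexed by gene ID with columns ``entropy`` (bits; NaN when
    undefined), ``normalized_entropy`` (score / log2 N) and ``class``.
    """

    frame: pd.DataFrame
    n_conditions: int | None = None

    @property
    def scores(self) -> pd.Series:
        """Defined scores only (excluded genes dropped)."""
        return self.frame["entropy"].dropna()

    @property
    def excluded_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["class"] == CLASS_EXCLUDED])

    @property
    def max_score(self) -> float | None:
        return None if self.n_conditions is None else float(np.log2(self.n_conditions))

    def __len__(self) -> int:
        return len(self.frame)


def compute_tpm(cm: CountMatrix) -> TPMMatrix:
    """Transcripts per million from gene-level counts and gene lengths.

    Per condition c: rate_g = count_gc / length_g, then
    TPM_gc = rate_g / sum_g rate_g * 1e6. A column with zero counts for every
    gene yields an all-zero TPM column (warning emitted).
    """
    lengths = cm.lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    counts = cm.counts.to_numpy(dtype=float)
    rates = counts / lengths[:, None]
    colsums = rates.sum(axis=0)
    empty = colsums == 0
    if empty.any():
        cols = [c for c, e in zip(cm.condition_ids, empty) if e]
        warnings.warn(f"all-zero count columns yield all-zero TPM: {cols}", stacklevel=2)
    safe = np.where(empty, 1.0, colsums)
    tpm = rates / safe[None, :] * 1e6
    tpm[:, empty] = 0.0
    return TPMMatrix(values=pd.DataFrame(tpm, index=cm.counts.index, columns=cm.counts.columns))


def condition_fractions(tpm_row: Sequence[float] | np.ndarray) -> FractionProfile:
    """Fractions of one gene's TPM across conditions.

    Undefined (``p is None``) exactly when the row sums to zero.
    """
    row = np.asarray(tpm_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("profile needs at least two conditions")
    if (row < 0).any():
        raise ValueError("TPM values must be nonnegative")
    total = row.sum()
    if total == 0:
        return FractionProfile(p=None, n=row.size)
    return FractionProfile(p=row / total, n=row.size)


def entropy_specificity(profile: FractionProfile) -> float:
    """Specificity score S = sum p*log2(p*N) in bits; NaN when undefined.

    Zero fractions contribute 0. The result is clamped at 0 against
    floating-point underflow; the analytic range is [0, log2 N].
    """
    if not profile.defined:
        return float("nan")
    p = profile.p
    nz = p > 0
    s = float(np.sum(p[nz] * np.log2(p[nz] * profile.n)))
    return max(s, 0.0)


def normalized_specificity(profile: FractionProfile) -> float:
    """Score scaled by its analytic maximum log2 N, so 0 = uniform and
    1 = single-condition."""
    return entropy_specificity(profile) / float(np.log2(profile.n))


def _vectorized_scores(values: np.ndarray) -> np.ndarray:
    """Row-wise S for a genes x conditions nonnegative matrix; NaN rows for
    all-zero genes. Exactly log2(N) - H(p) per row."""
    n = values.shape[1]
    totals = values.sum(axis=1)
    defined = totals > 0
    scores = np.full(values.shape[0], np.nan)
    if defined.any():
        p = values[defined] / totals[defined, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        h = -plogp.sum(axis=1)
        scores[defined] = np.maximum(np.log2(n) - h, 0.0)
    return scores


def compute_entropy_table(
    tpm: TPMMatrix, threshold: float = DEFAULT_THRESHOLD
) -> EntropyTable:
    """Score and classify every gene in a TPM matrix.

    Genes with zero TPM in all conditions get class ``excluded`` and NaN
    scores. Defined scores at or below ``threshold`` (default 1 bit) are
    ``constitutive-like``; scores strictly above are ``condition-specific``.
    """
    n = tpm.n_conditions
    if n < 2:
        raise ValueError("at least two conditions are required")
    scores = _vectorized_scores(tpm.values.to_numpy(dtype=float))
    maxs = float(np.log2(n))
    labels = np.where(
        np.isnan(scores),
        CLASS_EXCLUDED,
        np.where(scores > threshold, CLASS_SPECIFIC, CLASS_CONSTITUTIVE),
    )
    frame = pd.DataFrame(
        {
            "entropy": scores,
            "normalized_entropy": scores / maxs,
            "class": labels,
        },
        index=tpm.values.index,
    )
    return EntropyTable(frame=frame, n_conditions=n)


def interval_fraction(table: EntropyTable, lo: float, hi: float) -> tuple[int, float]:
    """Count and fraction of scored genes with lo <= S <= hi.

    The denominator is the number of scored (non-excluded) genes.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    scored = table.scores
    if scored.empty:
        raise ValueError("no scored genes in table")
    count = int(((scored >= lo) & (scored <= hi)).sum())
    return count, count / len(scored)
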