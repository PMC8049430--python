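"""Synthetic count matrices with known per-gene expression classes.

The generator emulates the structure the analysis assumes in a real
genes x conditions RNA-seq count matrix: constitutive genes with the same
expected expression everywhere, induced genes boosted in a few conditions,
strictly single-condition genes, and silent (all-zero) genes. Counts are
drawn from a negative binomial — the standard overdispersed count model for
bulk RNA-seq — with the expected count scaled by gene length so that TPM
normalization is exercised non-trivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from .io import CountMatrix
from .metric import CLASS_EXCLUDED, EntropyTable

CLASSES = ("constitutive", "induced", "single_condition", "silent")


@dataclass
class SyntheticSpec:
    """Parameters of the generator.

    Defaults mirror a 97-condition compendium: a 70/20/9/1 percent mix of
    constitutive, induced, single-condition and silent genes (echoing the
    roughly 70/30 low/high score split and ~1% unscoreable genes seen in a
    real genome-wide compendium), baseline expected count 100, negative
    binomial size 10, 100-fold induction in 2 of 97 conditions, and gene
    lengths uniform on 500–5000 bp.
    """

    n_genes: int = 5000
    n_conditions: int = 97
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.70,
            "induced": 0.20,
            "single_condition": 0.09,
            "silent": 0.01,
        }
    )
    base_mean: float = 100.0
    dispersion: float = 10.0  # NB size parameter; variance = m + m^2/size
    induction_fold: float = 100.0
    n_induced_conditions: int = 2
    length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_genes < 1:
            errors.append("n_genes must be positive")
        if self.n_conditions < 2:
            errors.append("n_conditions must be >= 2")
        if set(self.proportions) != set(CLASSES):
            errors.append(f"proportions must cover exactly {CLASSES}")
        elif any(v < 0 for v in self.proportions.values()):
            errors.append("proportions must be nonnegative")
        elif abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            errors.append("proportions must sum to 1")
        if self.base_mean <= 0:
            errors.append("base_mean must be positive")
        if self.dispersion <= 0:
            errors.append("dispersion must be positive")
        if self.induction_fold <= 1:
            errors.append("induction_fold must exceed 1")
        if not (1 <= self.n_induced_conditions < self.n_conditions):
            errors.append("n_induced_conditions must be in [1, n_conditions)")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            errors.append("length_range must satisfy 0 < min <= max")
        if errors:
            raise ValueError("invalid synthetic spec: " + "; ".join(errors))

    @classmethod
    def from_config(cls, path: str | Path) -> "SyntheticSpec":
        """Load a spec from a YAML (or JSON) key-value file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of spec fields")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown spec fields {sorted(unknown)}")
        if "length_range" in data:
            data["length_range"] = tuple(data["length_range"])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """True class label per gene and, for induced genes, the induced
    conditions."""

    labels: pd.Series  # index: gene IDs; values in CLASSES
    induced_conditions: dict[str, tuple[str, ...]]

    def class_counts(self) -> dict[str, int]:
        counts = self.labels.value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASSES}


@dataclass
class RecoveryMetrics:
    """How well the score recovers the generator's truth labels.

    ``median_scores`` maps each true class to its median score (None when the
    class is absent or unscored); ``auroc`` discriminates induced-or-single
    genes from constitutive ones (None when either side is absent);
    ``excluded_agreement`` is the fraction of silent genes the metric
    excluded (must be 1.0 for a correct pipeline).
    """

    median_scores: dict[str, float | None]
    auroc: float | None
    excluded_agreement: float | None


def _class_counts(spec: SyntheticSpec) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes over the class mix."""
    raw = {c: spec.proportions[c] * spec.n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = spec.n_genes - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean and size; mean 0 gives exact 0."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def generate_counts(spec: SyntheticSpec) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix and its truth labels from a single seeded stream.

    Expected count for gene g in condition c is
    base_mean * length_g / mean(length) * multiplier, where the multiplier is
    1 for constitutive genes, ``induction_fold`` in an induced gene's induced
    conditions, ``induction_fold`` in a single-condition gene's one active
    condition (0 elsewhere), and 0 everywhere for silent genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts_per_class = _class_counts(spec)
    width = max(5, len(str(spec.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    condition_ids = [f"C{j:03d}" for j in range(1, spec.n_conditions + 1)]

    labels = np.repeat(
        [c for c in CLASSES], [counts_per_class[c] for c in CLASSES]
    )
    rng.shuffle(labels)

    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    scale = spec.base_mean * lengths / lengths.mean()

    means = np.zeros((spec.n_genes, spec.n_conditions))
    induced_conditions: dict[str, tuple[str, ...]] = {}
    for i, (gid, label) in enumerate(zip(gene_ids, labels)):
        if label == "constitutive":
            means[i, :] = scale[i]
        elif label == "induced":
            means[i, :] = scale[i]
            cols = rng.choice(
                spec.n_conditions, size=spec.n_induced_conditions, replace=False
            )
            means[i, cols] *= spec.induction_fold
            induced_conditions[gid] = tuple(condition_ids[c] for c in sorted(cols))
        elif label == "single_condition":
            col = rng.integers(spec.n_conditions)
            means[i, col] = scale[i] * spec.induction_fold
        # silent: means stay 0

    counts = _nb_draw(rng, means, spec.dispersion)
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=condition_ids)
    cm = CountMatrix(counts=frame, lengths=pd.Series(lengths, index=frame.index))
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=frame.index, name="class"),
        induced_conditions=induced_conditions,
    )
    return cm, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    out = truth.labels.to_frame()
    out["induced_conditions"] = [
        ",".join(truth.induced_conditions.get(g, ())) for g in out.index
    ]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gene_id")
    induced = {
        g: tuple(cell.split(","))
        for g, cell in df["induced_conditions"].items()
        if isinstance(cell, str) and cell
    }
    return SyntheticTruth(labels=df["class"], induced_conditions=induced)


def recovery_metrics(table: EntropyTable, truth: SyntheticTruth) -> RecoveryMetrics:
    """Score the pipeline's recovery of the generator's truth labels."""
    if set(table.frame.index) != set(truth.labels.index):
        raise ValueError("entropy table and truth cover different genes")
    labels = truth.labels.loc[table.frame.index]
    scores = table.frame["entropy"]

    medians: dict[str, float | None] = {}
    for cls in CLASSES:
        vals = scores[labels == cls].dropna()
        medians[cls] = float(vals.median()) if len(vals) else None

    specific = labels.isin(["induced", "single_condition"])
    constitutive = labels == "constitutive"
    defined = scores.notna()
    pos = specific & defined
    neg = constitutive & defined
    auroc: float | None = None
    if pos.any() and neg.any():
        mask = pos | neg
        auroc = float(roc_auc_score(pos[mask].to_numpy(), scores[mask].to_numpy()))

    silent = labels == "silent"
    agreement: float | None = None
    if silent.any():
        excl = table.frame["class"] == CLASS_EXCLUDED
        agreement = float((excl[silent]).mean())
    return RecoveryMetrics(median_scores=medians, auroc=auroc, excluded_agreement=agreement)


def summary_json(metrics: RecoveryMetrics) -> str:
    return json.dumps(
        {
            "median_scores": metrics.median_scores,
            "auroc": metrics.auroc,
            "excluded_agreement": metrics.excluded_agreement,
        },
        indent=2,
    )
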