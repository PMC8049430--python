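"""Readers and writers for the tabular formats the pipeline touches.

The pipeline consumes gene-level count tables in the featureCounts dialect
(six annotation columns ``Geneid Chr Start End Strand Length`` followed by
one count column per sample, with ``#``-prefixed comment lines), a condition
metadata table grouping samples into biological conditions, plain-text gene
sets (one identifier per line) and an optional two-column identifier map. It
emits the per-gene entropy table as TSV.
"""

from __future__ import annotations

import io as _io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyGeneSetError, FormatError, UnmappedSampleError

ANNOTATION_COLUMNS = ("Geneid", "Chr", "Start", "End", "Strand", "Length")
CATEGORIES = ("Metabolism", "Development", "Light Response")

_ALIGNMENT_SUFFIXES = (".bam", ".sam", ".cram")


@dataclass
class CountMatrix:
    """Genes x conditions integer read counts with per-gene lengths.

    ``counts`` is indexed by gene ID with one column per condition (or per
    sample, before replicate merging); ``lengths`` holds the gene length in
    base pairs on the same index.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene IDs: {list(dupes)[:5]}")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate condition/sample IDs")
        if not self.lengths.index.equals(self.counts.index):
            raise FormatError("length index does not match count index")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be nonnegative")
        if (self.lengths.to_numpy() <= 0).any():
            raise FormatError("gene lengths must be positive")
        self.lengths = self.lengths.astype(np.int64).rename("length")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ConditionTable:
    """Condition metadata: each condition groups one or more sample IDs.

    ``category`` is one of Metabolism, Development or Light Response.
    Every sample ID may belong to exactly one condition.
    """

    frame: pd.DataFrame  # columns: condition_id, sample_ids (list), description, category

    def __post_init__(self) -> None:
        required = {"condition_id", "sample_ids", "description", "category"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"condition table missing columns: {sorted(missing)}")
        if self.frame["condition_id"].duplicated().any():
            raise FormatError("duplicate condition IDs")
        bad = set(self.frame["category"]) - set(CATEGORIES)
        if bad:
            raise FormatError(f"unknown categories: {sorted(bad)}")
        seen: dict[str, str] = {}
        for cond, samples in zip(self.frame["condition_id"], self.frame["sample_ids"]):
            for s in samples:
                if s in seen:
                    raise FormatError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {cond!r}"
                    )
                seen[s] = cond
        self._sample_to_condition = seen

    @property
    def condition_ids(self) -> list[str]:
        return list(self.frame["condition_id"])

    def sample_to_condition(self) -> dict[str, str]:
        return dict(self._sample_to_condition)

    def categories(self, condition_ids: Sequence[str]) -> list[str]:
        lookup = dict(zip(self.frame["condition_id"], self.frame["category"]))
        return [lookup[c] for c in condition_ids]


@dataclass
class GeneSet:
    """A named list of gene identifiers; duplicates removed on construction."""

    name: str
    gene_ids: list[str]
    n_duplicates: int = 0
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unique = list(dict.fromkeys(self.gene_ids))
        self.n_duplicates += len(self.gene_ids) - len(unique)
        self.gene_ids = unique
        if not self.gene_ids:
            raise EmptyGeneSetError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def merge(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        """Union of two sets, preserving first-seen order."""
        return GeneSet(
            name=name or f"{self.name}+{other.name}",
            gene_ids=self.gene_ids + other.gene_ids,
        )


def _normalize_sample_name(name: str) -> str:
    base = os.path.basename(name.strip())
    root, ext = os.path.splitext(base)
    if ext.lower() in _ALIGNMENT_SUFFIXES:
        return root
    return base


def read_featurecounts(path: str | Path) -> CountMatrix:
    """Parse a featureCounts gene-level output table.

    Comment lines beginning with ``#`` are skipped. The header must start
    with the six canonical annotation columns; only ``Geneid`` and ``Length``
    are used. Sample column headers that are file paths are reduced to their
    basename (minus any alignment-file extension).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no header line found")
    text = "".join(lines)
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    if df.shape[1] == 1:  # whitespace-delimited dialect
        df = pd.read_csv(_io.StringIO(text), sep=r"\s+", dtype=str)
    header = tuple(df.columns[: len(ANNOTATION_COLUMNS)])
    if header != ANNOTATION_COLUMNS:
        raise FormatError(
            f"{path}: expected annotation columns {ANNOTATION_COLUMNS}, got {header}"
        )
    sample_cols = list(df.columns[len(ANNOTATION_COLUMNS) :])
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns after annotation columns")
    if df["Geneid"].duplicated().any():
        dupes = df.loc[df["Geneid"].duplicated(), "Geneid"].unique()
        raise FormatError(f"{path}: duplicate Geneid rows: {list(dupes)[:5]}")
    try:
        lengths = df["Length"].astype(np.int64)
        counts = df[sample_cols].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer Length or count cell: {exc}") from exc
    counts.index = pd.Index(df["Geneid"], name="gene_id")
    lengths.index = counts.index
    counts.columns = [_normalize_sample_name(c) for c in sample_cols]
    return CountMatrix(counts=counts, lengths=lengths)


def write_featurecounts(cm: CountMatrix, path: str | Path, comment: str | None = None) -> None:
    """Write a count matrix in the featureCounts dialect accepted by
    :func:`read_featurecounts`. Chr/Start/End/Strand are placeholders."""
    path = Path(path)
    n = len(cm.gene_ids)
    out = pd.DataFrame(
        {
            "Geneid": cm.gene_ids,
            "Chr": ["chr1"] * n,
            "Start": np.arange(1, n + 1),
            "End": np.arange(1, n + 1) + cm.lengths.to_numpy() - 1,
            "Strand": ["+"] * n,
            "Length": cm.lengths.to_numpy(),
        }
    )
    for c in cm.condition_ids:
        out[c] = cm.counts[c].to_numpy()
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_condition_table(path: str | Path) -> ConditionTable:
    """Read condition metadata: TSV with columns ``condition_id``,
    ``sample_ids`` (comma-joined), ``description``, ``category``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_ids" not in df.columns:
        raise FormatError(f"{path}: missing sample_ids column")
    df["sample_ids"] = [
        [s.strip() for s in cell.split(",") if s.strip()] for cell in df["sample_ids"]
    ]
    return ConditionTable(frame=df)


def write_condition_table(ct: ConditionTable, path: str | Path) -> None:
    out = ct.frame.copy()
    out["sample_ids"] = [",".join(s) for s in out["sample_ids"]]
    out.to_csv(path, sep="\t", index=False)


def merge_replicates(cm: CountMatrix, ct: ConditionTable) -> CountMatrix:
    """Collapse sample columns into condition columns by summing counts.

    Gene-level read counts are additive over reads, so summing count columns
    is exactly equivalent to merging alignment files before counting.
    Conditions with no member sample present in ``cm`` are dropped with a
    warning; samples absent from the table raise :class:`UnmappedSampleError`.
    """
    mapping = ct.sample_to_condition()
    unmapped = [s for s in cm.condition_ids if s not in mapping]
    if unmapped:
        raise UnmappedSampleError(unmapped)
    merged: dict[str, np.ndarray] = {}
    for cond, samples in zip(ct.frame["condition_id"], ct.frame["sample_ids"]):
        present = [s for s in samples if s in cm.counts.columns]
        if not present:
            warnings.warn(
                f"condition {cond!r} has no member sample in the count matrix; dropped",
                stacklevel=2,
            )
            continue
        merged[cond] = cm.counts[present].sum(axis=1).to_numpy()
    out = pd.DataFrame(merged, index=cm.counts.index)
    return CountMatrix(counts=out, lengths=cm.lengths.copy())


def read_idmap(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping one identifier namespace to another."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: idmap needs two columns")
    src, dst = df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()
    if src.duplicated().any():
        dupes = src[src.duplicated()].unique()
        raise FormatError(f"{path}: source IDs mapped twice: {list(dupes)[:5]}")
    return dict(zip(src, dst))


def read_gene_set(
    path: str | Path,
    name: str | None = None,
    idmap: Mapping[str, str] | None = None,
) -> GeneSet:
    """Read a plain-text gene set, one identifier per line.

    Blank lines are ignored. If ``idmap`` is given, identifiers are
    translated; identifiers with no mapping are kept on the returned set's
    ``unmapped`` attribute rather than silently dropped.
    """
    path = Path(path)
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip()]
    unmapped: list[str] = []
    if idmap is not None:
        translated = []
        for gid in ids:
            if gid in idmap:
                translated.append(idmap[gid])
            else:
                unmapped.append(gid)
        ids = translated
    if not ids:
        raise EmptyGeneSetError(f"{path}: no identifiers remain after filtering")
    return GeneSet(name=name or path.stem, gene_ids=ids, unmapped=unmapped)


# Entropy-table serialization. %.12g keeps scores reproducible to well below
# the 1e-9 round-trip tolerance at the magnitudes the score can take.
_SCORE_FMT = "%.12g"
_ENTROPY_COLUMNS = ("gene_id", "entropy", "normalized_entropy", "class")


def write_entropy_table(table, path: str | Path) -> None:
    """Write an entropy table as TSV.

    Columns: gene_id, entropy, normalized_entropy, class. Undefined scores
    (all-zero genes) are written as ``NA`` with class ``excluded``.
    """
    df = table.frame.reset_index()
    df.columns = list(_ENTROPY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=_SCORE_FMT, na_rep="NA")


def read_entropy_table(path: str | Path):
    """Read back a TSV written by :func:`write_entropy_table`."""
    from .metric import EntropyTable

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "class": str}, na_values=["NA"])
    missing = set(_ENTROPY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.set_index("gene_id")
    return EntropyTable(frame=df)
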