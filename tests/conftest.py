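import numpy as np
import pandas as pd
import pytest

from condentropy import CountMatrix, ConditionTable


def make_count_matrix(counts, gene_ids=None, sample_ids=None, lengths=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    lengths = lengths if lengths is not None else [1000] * n_genes
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return CountMatrix(counts=frame, lengths=pd.Series(lengths, index=frame.index))


def make_condition_table(groups, categories=None):
    """groups: dict condition_id -> list of sample ids."""
    cats = categories or {}
    frame = pd.DataFrame(
        {
            "condition_id": list(groups),
            "sample_ids": [list(v) for v in groups.values()],
            "description": ["" for _ in groups],
            "category": [cats.get(c, "Metabolism") for c in groups],
        }
    )
    return ConditionTable(frame=frame)


@pytest.fixture
def featurecounts_file(tmp_path):
    """Write a featureCounts-dialect table; returns (path, writer)."""

    def write(rows, samples, comment="Program:featureCounts v1.6.2; synthetic fixture", name="counts.tsv"):
        # rows: list of (geneid, length, counts...)
        path = tmp_path / name
        header = "\t".join(["Geneid", "Chr", "Start", "End", "Strand", "Length"] + samples)
        lines = [f"# {comment}", header]
        for gid, length, *counts in rows:
            lines.append(
                "\t".join([gid, "chr1", "1", str(length), "+", str(length)] + [str(c) for c in counts])
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture
def toy_counts():
    return make_count_matrix(
        [[10, 12, 0, 0], [10, 9, 11, 10], [0, 0, 0, 0]],
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["c1", "c2", "c3", "c4"],
        lengths=[1000, 2000, 500],
    )
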