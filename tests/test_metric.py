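"""TPM normalization and the specificity score: examples, invariants, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import condentropy as ce
from condentropy.metric import (
    CLASS_CONSTITUTIVE,
    CLASS_EXCLUDED,
    CLASS_SPECIFIC,
    _vectorized_scores,
)

from conftest import make_count_matrix


def naive_score(p):
    """Independent per-term oracle: S = sum p*log2(p*N), 0*log0 = 0."""
    n = len(p)
    total = 0.0
    for v in p:
        if v > 0:
            total += v * np.log2(v * n)
    return total


class TestComputeTpm:
    def test_single_gene_forced_to_million(self):
        cm = make_count_matrix([[7]], lengths=[1234])
        tpm = ce.compute_tpm(cm)
        assert tpm.values.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_hand_computed(self):
        # rates 10/1000 = 0.01 and 10/2000 = 0.005; fractions 2/3 and 1/3
        cm = make_count_matrix([[10], [10]], lengths=[1000, 2000])
        tpm = ce.compute_tpm(cm)
        assert tpm.values.iloc[0, 0] == pytest.approx(666666.667, abs=0.01)
        assert tpm.values.iloc[1, 0] == pytest.approx(333333.333, abs=0.01)

    def test_all_zero_column_stays_zero(self):
        cm = make_count_matrix([[5, 0], [3, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = ce.compute_tpm(cm)
        assert (tpm.values.iloc[:, 1] == 0).all()

    def test_nonempty_columns_sum_to_million(self):
        rng = np.random.default_rng(5)
        cm = make_count_matrix(
            rng.integers(0, 200, size=(30, 8)), lengths=list(rng.integers(100, 9000, 30))
        )
        sums = ce.compute_tpm(cm).values.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)


class TestConditionFractions:
    def test_fractions(self):
        prof = ce.condition_fractions([5, 5, 0, 0])
        np.testing.assert_allclose(prof.p, [0.5, 0.5, 0, 0])

    def test_zero_row_undefined(self):
        prof = ce.condition_fractions([0, 0, 0])
        assert not prof.defined and prof.n == 3

    def test_scale_invariance(self):
        a = ce.condition_fractions([1.0, 2.0, 3.0])
        b = ce.condition_fractions([2.5, 5.0, 7.5])
        np.testing.assert_allclose(a.p, b.p)

    def test_single_condition_row_rejected(self):
        with pytest.raises(ValueError):
            ce.condition_fractions([5.0])


class TestEntropySpecificity:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(97, 1 / 97), 0.0),
            ([1.0] + [0.0] * 96, np.log2(97)),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
            ([0.5, 0.25, 0.25], 0.5 * np.log2(1.5) + 0.5 * np.log2(0.75)),
        ],
        ids=["uniform", "single-condition", "half-half", "skewed-three"],
    )
    def test_reference_values(self, p, expected):
        prof = ce.FractionProfile(p=np.asarray(p, dtype=float), n=len(p))
        assert ce.entropy_specificity(prof) == pytest.approx(expected, abs=1e-12)

    def test_skewed_three_matches_hand_sum(self):
        prof = ce.FractionProfile(p=np.array([0.5, 0.25, 0.25]), n=3)
        assert ce.entropy_specificity(prof) == pytest.approx(0.08496, abs=5e-6)

    def test_undefined_profile_gives_nan(self):
        assert np.isnan(ce.entropy_specificity(ce.FractionProfile(p=None, n=5)))

    def test_normalized_examples(self):
        single = ce.FractionProfile(p=np.array([0.0, 1.0, 0.0]), n=3)
        assert ce.normalized_specificity(single) == pytest.approx(1.0)
        half = ce.FractionProfile(p=np.array([0.5, 0.5, 0.0, 0.0]), n=4)
        assert ce.normalized_specificity(half) == pytest.approx(0.5)
        uniform = ce.FractionProfile(p=np.full(6, 1 / 6), n=6)
        assert ce.normalized_specificity(uniform) == pytest.approx(0.0, abs=1e-12)

    def test_vectorized_matches_naive_loop_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            n_genes = rng.integers(1, 21)
            n_cond = rng.integers(2, 11)
            mat = rng.random((n_genes, n_cond)) * rng.integers(1, 1000)
            mat[rng.random(mat.shape) < 0.3] = 0.0
            scores = _vectorized_scores(mat)
            for i in range(n_genes):
                row = mat[i]
                if row.sum() == 0:
                    assert np.isnan(scores[i])
                else:
                    assert scores[i] == pytest.approx(
                        naive_score(row / row.sum()), abs=1e-12
                    )

    def test_monotone_in_concentration(self):
        # p = (q, uniform remainder): score strictly increases with q > 1/N
        n = 12
        grid = np.linspace(1 / n + 0.01, 1.0, 60)
        scores = []
        for q in grid:
            p = np.full(n, (1 - q) / (n - 1))
            p[0] = q
            scores.append(ce.entropy_specificity(ce.FractionProfile(p=p, n=n)))
        assert np.all(np.diff(scores) > 0)


@st.composite
def tpm_rows(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    elements = st.one_of(
        st.just(0.0), st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
    )
    row = draw(hnp.arrays(float, n, elements=elements))
    return row


class TestScoreProperties:
    @given(tpm_rows())
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_decomposition(self, row):
        prof = ce.condition_fractions(row)
        if not prof.defined:
            return
        s = ce.entropy_specificity(prof)
        n = prof.n
        assert 0.0 <= s <= np.log2(n) + 1e-9
        h = -sum(v * np.log2(v) for v in prof.p if v > 0)
        assert s + h == pytest.approx(np.log2(n), abs=1e-9)

    @given(tpm_rows(), st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance(self, row, rnd):
        prof = ce.condition_fractions(row)
        if not prof.defined:
            return
        perm = list(range(len(row)))
        rnd.shuffle(perm)
        shuffled = ce.condition_fractions(row[perm])
        assert ce.entropy_specificity(shuffled) == pytest.approx(
            ce.entropy_specificity(prof), abs=1e-12
        )

    @given(tpm_rows(), st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=100)
    def test_row_scale_invariance(self, row, c):
        prof = ce.condition_fractions(row)
        if not prof.defined:
            return
        scaled = ce.condition_fractions(row * c)
        assert ce.entropy_specificity(scaled) == pytest.approx(
            ce.entropy_specificity(prof), abs=1e-9
        )


class TestEntropyTable:
    def test_zero_gene_excluded_and_listed(self, toy_counts):
        table = ce.compute_entropy_table(ce.compute_tpm(toy_counts))
        assert table.excluded_ids == ["gC"]
        assert table.frame.loc["gC", "class"] == CLASS_EXCLUDED
        assert len(table.scores) == 2

    def test_threshold_classification(self):
        # gA expressed in 1 of 4 conditions: S = 2 bits -> condition-specific;
        # gB uniform: S = 0 -> constitutive-like
        cm = make_count_matrix([[40, 0, 0, 0], [10, 10, 10, 10]])
        table = ce.compute_entropy_table(ce.compute_tpm(cm))
        assert table.frame.loc["g1", "class"] == CLASS_SPECIFIC
        assert table.frame.loc["g2", "class"] == CLASS_CONSTITUTIVE

    def test_boundary_score_is_constitutive(self):
        # exactly half/half over 4 conditions gives S = 1.0, read as "not above one"
        cm = make_count_matrix([[10, 10, 0, 0], [10, 10, 10, 10]])
        table = ce.compute_entropy_table(ce.compute_tpm(cm))
        assert table.frame.loc["g1", "entropy"] == pytest.approx(1.0, abs=1e-12)
        assert table.frame.loc["g1", "class"] == CLASS_CONSTITUTIVE

    def test_single_condition_table_rejected(self):
        cm = make_count_matrix([[5], [3]])
        with pytest.raises(ValueError, match="two conditions"):
            ce.compute_entropy_table(ce.compute_tpm(cm))


class TestIntervalFraction:
    def _table_from_scores(self, scores):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "entropy": scores,
                "normalized_entropy": np.asarray(scores) / np.log2(8),
                "class": [CLASS_CONSTITUTIVE] * len(scores),
            },
            index=pd.Index([f"g{i}" for i in range(len(scores))], name="gene_id"),
        )
        return ce.EntropyTable(frame=frame, n_conditions=8)

    def test_simple_interval(self):
        count, frac = ce.interval_fraction(self._table_from_scores([0.1, 0.5, 2.0]), 0.05, 1)
        assert (count, frac) == (2, pytest.approx(2 / 3))

    def test_full_interval_is_total(self):
        table = self._table_from_scores([0.1, 0.5, 2.0, 2.9])
        count, frac = ce.interval_fraction(table, 0, np.log2(8))
        assert (count, frac) == (4, 1.0)

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(0, 3, size=1000)
        table = self._table_from_scores(scores)
        for _ in range(20):
            lo, hi = sorted(rng.uniform(0, 3, size=2))
            count, frac = ce.interval_fraction(table, lo, hi)
            brute = sum(1 for s in scores if lo <= s <= hi)
            assert count == brute and frac == pytest.approx(brute / 1000)

    def test_excluded_genes_not_in_denominator(self, toy_counts):
        table = ce.compute_entropy_table(ce.compute_tpm(toy_counts))
        _, frac = ce.interval_fraction(table, 0, 10)
        assert frac == 1.0  # denominator is the 2 scored genes, not 3
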