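import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleopairs.cooccur import (
    NullEngineConfig,
    c_score,
    classify_pairs,
    pair_census,
    swap_null_matrix,
)
from paleopairs.occurrences import OccurrenceMatrix

from conftest import random_binary_matrix


def enumerate_fixed_margin_matrices(row_sums, col_sums):
    """Independent oracle: every binary matrix with the given marginals,
    by exhaustive row-wise recursion. Only usable for tiny matrices."""
    from itertools import combinations

    n_cols = len(col_sums)
    out = []

    def rec(i, remaining_cols, rows):
        if i == len(row_sums):
            if all(c == 0 for c in remaining_cols):
                out.append(np.array(rows, dtype=np.int8))
            return
        cols_left = [j for j in range(n_cols) if remaining_cols[j] > 0]
        for chosen in combinations(cols_left, row_sums[i]):
            row = [0] * n_cols
            rem = list(remaining_cols)
            for j in chosen:
                row[j] = 1
                rem[j] -= 1
            # feasibility: remaining capacity must cover remaining row sums
            if sum(rem) == sum(row_sums[i + 1:]):
                rec(i + 1, rem, rows + [row])

    rec(0, list(col_sums), [])
    return out


class TestCScore:
    def test_complete_aggregation_is_zero(self):
        assert c_score(5, 5, 5) == 0.0

    def test_complete_segregation_is_one(self):
        assert c_score(4, 6, 0) == 1.0

    def test_hand_value(self):
        assert c_score(4, 2, 1) == pytest.approx(0.375)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            c_score(0, 3, 0)
        with pytest.raises(ValueError):
            c_score(4, 2, 3)
        with pytest.raises(ValueError):
            c_score(4, 2, -1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_and_range(self, data):
        r_i = data.draw(st.integers(1, 30))
        r_j = data.draw(st.integers(1, 30))
        d = data.draw(st.integers(0, min(r_i, r_j)))
        c = c_score(r_i, r_j, d)
        assert c == c_score(r_j, r_i, d)
        assert 0.0 <= c <= 1.0


class TestSwapNull:
    def test_marginals_conserved(self):
        rng = np.random.default_rng(0)
        m = random_binary_matrix(rng, 12, 9, fill=0.3)
        out = swap_null_matrix(m, 500, seed=1)
        assert np.array_equal(out.row_totals, m.row_totals)
        assert np.array_equal(out.col_totals, m.col_totals)
        assert not np.array_equal(out.cells, m.cells)  # it actually moved

    def test_2x2_identity_one_swap_gives_antidiagonal(self):
        m = OccurrenceMatrix(["a", "b"], ["s1", "s2"], np.eye(2, dtype=int), "Cf3")
        out = swap_null_matrix(m, 1, seed=0)
        assert out.cells.tolist() == [[0, 1], [1, 0]]

    def test_single_row_matrix_unchanged(self):
        m = OccurrenceMatrix(["a"], ["s1", "s2", "s3"], np.ones((1, 3), int), "Cf3")
        out = swap_null_matrix(m, 100, seed=0)
        assert np.array_equal(out.cells, m.cells)

    def test_full_matrix_has_no_checkerboard(self):
        m = OccurrenceMatrix(["a", "b"], ["s1", "s2"], np.ones((2, 2), int), "Cf3")
        out = swap_null_matrix(m, 5, seed=0)
        assert np.array_equal(out.cells, m.cells)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_marginal_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng, rng.integers(2, 10), rng.integers(2, 10))
        out = swap_null_matrix(m, 200, seed=seed)
        assert np.array_equal(out.row_totals, m.row_totals)
        assert np.array_equal(out.col_totals, m.col_totals)

    def test_swap_chain_matches_enumeration_oracle(self):
        """On a tiny matrix the thinned swap chain should sample the uniform
        distribution over same-marginal matrices: compare the chain's
        distribution of a pair's shared-site count D against exhaustive
        enumeration (total variation)."""
        cells = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=np.int8)
        m = OccurrenceMatrix(["a", "b", "c"], ["s1", "s2", "s3"], cells, "Cf3")
        universe = enumerate_fixed_margin_matrices(
            m.row_totals.tolist(), m.col_totals.tolist()
        )
        exact = pd.Series(
            [int((u[0] * u[1]).sum()) for u in universe], dtype=int
        ).value_counts(normalize=True)

        rng = np.random.default_rng(5)
        from paleopairs.cooccur import _attempt_swaps, _rows_as_lists

        rows = _rows_as_lists(m.cells)
        thin = int(m.cells.sum())
        _attempt_swaps(rows, 10 * thin, rng)
        samples = []
        for _ in range(3000):
            _attempt_swaps(rows, thin, rng)
            a = np.asarray(rows)
            samples.append(int((a[0] * a[1]).sum()))
        sampled = pd.Series(samples).value_counts(normalize=True)
        support = sorted(set(exact.index) | set(sampled.index))
        tv = 0.5 * sum(
            abs(exact.get(v, 0.0) - sampled.get(v, 0.0)) for v in support
        )
        assert tv < 0.1


class TestClassifyPairs:
    def test_planted_identical_pair_is_aggregated(self):
        rng = np.random.default_rng(11)
        n_sites = 20
        bg = (rng.random((30, n_sites)) < 0.5).astype(np.int8)
        shared = np.zeros(n_sites, dtype=np.int8)
        shared[:10] = 1
        cells = np.vstack([shared, shared, bg])
        m = OccurrenceMatrix(
            [f"sp{i:02d}" for i in range(32)],
            [f"s{j:02d}" for j in range(n_sites)],
            cells,
            "Cf3",
        ).validated()
        res = classify_pairs(m, NullEngineConfig(n_null=500, seed=3))
        row = res[(res.species_i == "sp00") & (res.species_j == "sp01")].iloc[0]
        assert row.classification == "aggregated" and row.p_agg <= 0.05
        assert row.c_score == 0.0

    def test_planted_disjoint_pair_is_segregated(self):
        rng = np.random.default_rng(12)
        n_sites = 20
        bg = (rng.random((30, n_sites)) < 0.5).astype(np.int8)
        left = np.zeros(n_sites, dtype=np.int8)
        left[:10] = 1
        right = 1 - left
        cells = np.vstack([left, right, bg])
        m = OccurrenceMatrix(
            [f"sp{i:02d}" for i in range(32)],
            [f"s{j:02d}" for j in range(n_sites)],
            cells,
            "Cf3",
        ).validated()
        res = classify_pairs(m, NullEngineConfig(n_null=500, seed=4))
        row = res[(res.species_i == "sp00") & (res.species_j == "sp01")].iloc[0]
        assert row.classification == "segregated" and row.p_seg <= 0.05
        assert row.c_score == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(13)
        m = random_binary_matrix(rng, 15, 12, fill=0.35)
        cfg = NullEngineConfig(n_null=200, seed=7)
        a = classify_pairs(m, cfg)
        b = classify_pairs(m, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_matrix_raises(self):
        m = OccurrenceMatrix(["a"], ["s1", "s2"], np.ones((1, 2), int), "Cf3")
        with pytest.raises(ValueError):
            classify_pairs(m, NullEngineConfig(n_null=100))

    def test_pvalues_not_anticonservative_on_null_matrices(self):
        """Matrices generated by the null itself should be flagged
        non-random in at most ~2*alpha of pairs (the discrete conditional
        test is conservative, never anti-conservative)."""
        rng = np.random.default_rng(14)
        flagged = total = 0
        for rep in range(10):
            m = random_binary_matrix(rng, 12, 15, fill=0.4)
            m = swap_null_matrix(m, 2000, seed=100 + rep)
            res = classify_pairs(m, NullEngineConfig(n_null=300, seed=rep))
            flagged += (res.classification != "random").sum()
            total += len(res)
        frac = flagged / total
        assert frac <= 0.10 + 2 * np.sqrt(0.1 * 0.9 / total)


class TestPairCensus:
    def test_counts_partition_all_pairs(self):
        rng = np.random.default_rng(15)
        m = random_binary_matrix(rng, 8, 10, fill=0.4)
        res = {"Cf3": classify_pairs(m, NullEngineConfig(n_null=150, seed=0))}
        census = pair_census(res)
        row = census.iloc[0]
        assert row.total_pairs == 28  # C(8, 2)
        assert row.aggregated + row.segregated + row.random == row.total_pairs
        assert row.total_significant == row.aggregated + row.segregated

    def test_bin_without_segregations_reports_zero(self):
        df = pd.DataFrame(
            {
                "species_i": ["a", "a", "b"],
                "species_j": ["b", "c", "c"],
                "classification": ["aggregated", "random", "random"],
            }
        )
        census = pair_census({"Wa0": df})
        assert census.iloc[0].segregated == 0
        assert census.iloc[0].total_significant == 1
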