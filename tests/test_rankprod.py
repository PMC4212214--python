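import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootshift import (
    RPConfig,
    Tissue,
    generate_null_dataset,
    pairwise_ratio_matrix,
    permutation_significance,
    rank_product_statistic,
    rank_product_test,
)

from .oracles import exhaustive_permutation_p, rank_product_by_hand


class TestPairwiseRatios:
    def test_single_replicates_give_one_column(self):
        a = np.array([[2.0], [8.0]])
        b = np.array([[1.0], [4.0]])
        ratios = pairwise_ratio_matrix(a, b)
        np.testing.assert_allclose(ratios, [[2.0], [2.0]])

    def test_identical_replicates_give_unit_ratios(self):
        a = np.array([[3.0], [7.0], [11.0]])
        np.testing.assert_allclose(pairwise_ratio_matrix(a, a), 1.0)

    def test_3v4_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(10, 1000, size=(6, 3))
        b = rng.uniform(10, 1000, size=(6, 4))
        ratios = pairwise_ratio_matrix(a, b)
        assert ratios.shape == (6, 12)
        for g in range(6):
            for i in range(3):
                for j in range(4):
                    assert ratios[g, i * 4 + j] == a[g, i] / b[g, j]

    def test_flooring_prevents_zero_division(self):
        a = np.array([[0.0], [5.0]])
        b = np.array([[0.0], [5.0]])
        np.testing.assert_allclose(pairwise_ratio_matrix(a, b, floor=1.0), 1.0)


class TestStatistic:
    def test_top_gene_has_rp_one_single_column(self):
        ratios = np.array([[9.0], [3.0], [1.0]])
        rp = rank_product_statistic(ratios, "up")
        assert rp[0] == 1.0
        np.testing.assert_allclose(rp, [1.0, 2.0, 3.0])

    def test_geometric_mean_of_ranks_by_hand(self):
        # gene 0 ranked 2 and 8 across two columns -> rp = sqrt(16) = 4
        col1 = np.array([8.0, 9, 7, 6, 5, 4, 3, 2, 1, 0.5])
        col2 = np.array([2.0, 9, 8, 7, 6, 5, 4, 3, 1, 0.5])
        rp = rank_product_statistic(np.column_stack([col1, col2]), "up")
        assert rp[0] == pytest.approx(4.0)

    def test_all_tied_column_gets_average_rank(self):
        ratios = np.ones((5, 1))
        np.testing.assert_allclose(rank_product_statistic(ratios, "up"), 3.0)

    def test_matches_hand_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        ratios = rng.choice([0.25, 0.5, 1.0, 2.0, 4.0], size=(8, 3))
        for direction in ("up", "down"):
            np.testing.assert_allclose(
                rank_product_statistic(ratios, direction),
                rank_product_by_hand(ratios, direction),
            )

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match="two genes"):
            rank_product_statistic(np.array([[2.0]]), "up")


class TestPermutationSignificance:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """4 genes x 2 columns: MC p within 3 standard errors of the exact
        pooled null enumerated over all (4!)^2 = 576 rank configurations."""
        rng = np.random.default_rng(12)
        ratios = rng.lognormal(0, 1, size=(4, 2))
        n, n_perm = 4, 10_000
        for direction in ("up", "down"):
            rp = rank_product_statistic(ratios, direction)
            p, _ = permutation_significance(ratios, rp, direction, n_perm, seed=99)
            exact_mean, exact_sd, _ = exhaustive_permutation_p(ratios, direction)
            p_expected = (1 + n_perm * exact_mean * n) / (1 + n_perm * n)
            se = np.sqrt(n_perm) * exact_sd * n / (1 + n_perm * n)
            assert np.all(np.abs(p - p_expected) <= 3 * se + 1e-9)

    def test_minimum_rp_has_smallest_p(self):
        rng = np.random.default_rng(8)
        ratios = rng.lognormal(0, 0.5, size=(20, 2))
        ratios[7] = [50.0, 60.0]  # forced overall winner: rp = 1
        rp = rank_product_statistic(ratios, "up")
        assert rp[7] == 1.0
        p, pfp = permutation_significance(ratios, rp, "up", 300, seed=1)
        assert p[7] == p.min()
        assert np.all(p > 0) and np.all(p <= 1)

    def test_p_monotone_in_rp(self):
        rng = np.random.default_rng(21)
        ratios = rng.lognormal(0, 1, size=(40, 4))
        rp = rank_product_statistic(ratios, "up")
        p, _ = permutation_significance(ratios, rp, "up", 200, seed=2)
        order = np.argsort(rp)
        assert np.all(np.diff(p[order]) >= 0)

    def test_pfp_is_p_scaled_by_rank_position(self):
        rng = np.random.default_rng(4)
        ratios = rng.lognormal(0, 1, size=(15, 2))
        rp = rank_product_statistic(ratios, "up")
        p, pfp = permutation_significance(ratios, rp, "up", 100, seed=3)
        from scipy.stats import rankdata

        np.testing.assert_allclose(pfp, p * 15 / rankdata(rp))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(17)
        ratios = rng.lognormal(0, 1, size=(30, 3))
        rp = rank_product_statistic(ratios, "up")
        p1, _ = permutation_significance(ratios, rp, "up", 100, seed=5)
        p2, _ = permutation_significance(ratios, rp, "up", 100, seed=5)
        np.testing.assert_array_equal(p1, p2)


class TestSymmetries:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_down_equals_up_on_reciprocal(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.lognormal(0, 1, size=(10, 3))
        np.testing.assert_allclose(
            rank_product_statistic(ratios, "down"),
            rank_product_statistic(1.0 / ratios, "up"),
        )

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), mode=st.sampled_from(["ranks", "arrays"]))
    def test_gene_permutation_invariance(self, seed, mode):
        """Permuting input gene order permutes p-values identically (the
        permutation stream depends only on the column value multisets)."""
        rng = np.random.default_rng(seed)
        a = rng.lognormal(5, 1, size=(12, 2))
        b = rng.lognormal(5, 1, size=(12, 2))
        ratios = pairwise_ratio_matrix(a, b)
        perm = rng.permutation(12)
        rp = rank_product_statistic(ratios, "up")
        rp_perm = rank_product_statistic(ratios[perm], "up")
        np.testing.assert_allclose(rp_perm, rp[perm])
        p, _ = permutation_significance(
            ratios, rp, "up", 50, seed=9, null_mode=mode, replicates=(a, b)
        )
        p_perm, _ = permutation_significance(
            ratios[perm], rp_perm, "up", 50, seed=9, null_mode=mode,
            replicates=(a[perm], b[perm]),
        )
        np.testing.assert_allclose(p_perm, p[perm])

    def test_rp_bounded_by_gene_count(self):
        rng = np.random.default_rng(2)
        ratios = rng.lognormal(0, 1, size=(25, 5))
        for direction in ("up", "down"):
            rp = rank_product_statistic(ratios, direction)
            assert np.all(rp >= 1.0) and np.all(rp <= 25.0)


def test_null_dataset_p_values_nearly_uniform():
    """Small-scale calibration: on null data the up-direction p-values are
    approximately uniform and ~1% of genes fall below p = 0.01."""
    ds = generate_null_dataset(1500, replicates=3, noise_cv=0.3, seed=42)
    a = ds.replicate_matrix(Tissue.STEM_BASE, 24.0)
    b = ds.replicate_matrix(Tissue.STEM_BASE, 0.0)
    ratios = pairwise_ratio_matrix(a, b)
    rp = rank_product_statistic(ratios, "up")
    p, _ = permutation_significance(
        ratios, rp, "up", 400, seed=0, null_mode="arrays", replicates=(a, b)
    )
    from scipy.stats import kstest

    assert kstest(p, "uniform").statistic < 0.04
    assert 0.003 <= (p < 0.01).mean() <= 0.025


def test_rank_product_test_result_structure(tiny_dataset):
    a = tiny_dataset.replicate_matrix(Tissue.STEM_BASE, 24.0)
    b = tiny_dataset.replicate_matrix(Tissue.STEM_BASE, 0.0)
    res = rank_product_test(a, b, tiny_dataset.gene_ids, RPConfig(50, 1))
    assert res.k == 9
    # gene 0 rises 4x, gene 2 falls 4x: extreme ranks in the right directions
    assert res.rp_up[0] == 1.0
    assert res.rp_down[2] == 1.0
    frame = res.to_frame()
    assert list(frame["gene_id"]) == tiny_dataset.gene_ids
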