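import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootshift import (
    Comparison,
    GeneAnnotation,
    RepresentationInput,
    RPConfig,
    Tissue,
    category_profile,
    compare_conditions,
    hormone_timecourse,
    representation_ratio,
)

from .oracles import recount_representation


class TestRatio:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 100, 1000, 10000), 1.0),
            ((20, 100, 1000, 10000), 2.0),
            ((0, 50, 1000, 10000), 0.0),
            ((5, 10, 100, 1000), 5.0),
        ],
    )
    def test_printed_formula(self, counts, expected):
        assert representation_ratio(RepresentationInput(*counts)) == pytest.approx(expected)

    def test_distinct_zero_denominator_messages(self):
        with pytest.raises(ValueError, match="n_xt"):
            representation_ratio(RepresentationInput(0, 0, 10, 100))
        with pytest.raises(ValueError, match="n_ap"):
            representation_ratio(RepresentationInput(0, 10, 0, 100))
        with pytest.raises(ValueError, match="n_at"):
            RepresentationInput(0, 0, 0, 0)

    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            RepresentationInput(20, 10, 100, 1000)  # n_xp > n_xt
        with pytest.raises(ValueError):
            RepresentationInput(5, 10, 2000, 1000)  # n_ap > n_at

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_xp=st.integers(0, 50),
        n_xt=st.integers(50, 200),
        n_ap=st.integers(50, 500),
        n_at=st.integers(500, 5000),
        scale=st.integers(1, 7),
    )
    def test_scale_invariance(self, n_xp, n_xt, n_ap, n_at, scale):
        base = representation_ratio(RepresentationInput(n_xp, n_xt, n_ap, n_at))
        scaled = representation_ratio(
            RepresentationInput(n_xp * scale, n_xt * scale, n_ap * scale, n_at * scale)
        )
        assert scaled == pytest.approx(base)


@pytest.fixture(scope="module")
def noisy_profile(noisy_run):
    ds, annotation, _ = noisy_run
    de = compare_conditions(
        ds,
        Comparison("sb72_vs_sb24", Tissue.STEM_BASE, 72.0, Tissue.STEM_BASE, 24.0),
        RPConfig(300, 8),
    )
    return de, annotation, category_profile(de, annotation)


class TestCategoryProfile:
    def test_matches_independent_recount(self, noisy_profile):
        """Every (category, direction) row equals a brute-force recount from
        the raw DE calls and annotation."""
        de, annotation, profile = noisy_profile
        for _, row in profile.iterrows():
            n_xp, n_xt, n_ap, n_at, ratio = recount_representation(
                de, annotation, row["category_code"], row["direction"]
            )
            assert (row["n_xp"], row["n_xt"], row["n_ap"], row["n_at"]) == (
                n_xp, n_xt, n_ap, n_at,
            )
            if not row["excluded"]:
                assert row["ratio"] == pytest.approx(ratio)

    def test_conservation_over_disjoint_categories(self, noisy_profile):
        """Categories partition the annotated universe: the n_xp sum to n_ap
        and the n_xt to n_at in each direction."""
        _, _, profile = noisy_profile
        for direction in ("up", "down"):
            rows = profile[profile["direction"] == direction]
            assert rows["n_xp"].sum() == rows["n_ap"].iloc[0]
            assert rows["n_xt"].sum() == rows["n_at"].iloc[0]

    def test_small_categories_excluded(self, noisy_profile):
        _, _, profile = noisy_profile
        small = profile[profile["n_xt"] < 10]
        assert len(small) > 0
        assert small["excluded"].all()
        assert (small["flag"] == "none").all()

    def test_two_fold_flags_match_ratios(self, noisy_profile):
        _, _, profile = noisy_profile
        kept = profile[~profile["excluded"]]
        assert ((kept["ratio"] >= 2.0) == (kept["flag"] == "over")).all()
        assert ((kept["ratio"] <= 0.5) == (kept["flag"] == "under")).all()

    def test_uniform_random_assignment_gives_unit_ratios(self):
        """Sampling null: with categories assigned independently of DE calls,
        ratios of large categories concentrate near 1."""
        rng = np.random.default_rng(15)
        n = 6000
        genes = [f"g{i}" for i in range(n)]
        calls = np.where(rng.random(n) < 0.1, "up", "ns")
        de = pd.DataFrame({"gene_id": genes, "comparison": "c", "call": calls})
        codes = rng.choice(["A", "B", "C"], size=n)  # ~2000 genes each
        ann = GeneAnnotation(
            pd.DataFrame(
                {"category_code": codes, "category_name": codes, "hormone_category": "none"},
                index=pd.Index(genes, name="gene_id"),
            )
        )
        profile = category_profile(de, ann)
        up = profile[(profile["direction"] == "up") & ~profile["excluded"]]
        assert (up["m"].abs() < 0.3).all()

    def test_empty_annotation_rejected(self, noisy_profile):
        de, _, _ = noisy_profile
        empty = GeneAnnotation(
            pd.DataFrame(
                columns=["category_code", "category_name", "hormone_category"],
                index=pd.Index([], name="gene_id"),
            )
        )
        with pytest.raises(ValueError, match="empty"):
            category_profile(de, empty)


class TestHormoneTimecourse:
    def test_planted_hormone_enrichment_flagged_over(self, noisy_run):
        """Ethylene genes are planted enriched among up-regulated genes of
        the reference window; the profile flags them over-represented."""
        ds, annotation, truth = noisy_run
        de = compare_conditions(
            ds,
            Comparison("sb72_vs_sb24", Tissue.STEM_BASE, 72.0, Tissue.STEM_BASE, 24.0),
            RPConfig(300, 8),
        )
        tc = hormone_timecourse({"sb72_vs_sb24": de}, annotation)
        eth = tc[(tc["hormone"] == "ethylene") & (tc["direction"] == "up")].iloc[0]
        assert not eth["excluded"]
        assert eth["flag"] == "over"

    def test_small_hormone_categories_excluded_everywhere(self, noisy_run):
        ds, annotation, _ = noisy_run
        de = compare_conditions(
            ds,
            Comparison("sb2_vs_sb0", Tissue.STEM_BASE, 2.0, Tissue.STEM_BASE, 0.0),
            RPConfig(60, 8),
        )
        tc = hormone_timecourse({"a": de, "b": de}, annotation)
        for hormone in ("cytokinin", "brassinosteroid", "salicylic_acid"):
            rows = tc[tc["hormone"] == hormone]
            assert len(rows) == 4  # 2 comparisons x 2 directions
            assert rows["excluded"].all()

    def test_annotation_without_hormones_rejected(self, noisy_run):
        ds, _, _ = noisy_run
        genes = ds.gene_ids[:5]
        ann = GeneAnnotation(
            pd.DataFrame(
                {"category_code": "A", "category_name": "a", "hormone_category": "none"},
                index=pd.Index(genes, name="gene_id"),
            )
        )
        de = pd.DataFrame({"gene_id": genes, "comparison": "c", "call": "ns"})
        with pytest.raises(ValueError, match="hormone"):
            hormone_timecourse({"c": de}, ann)


def test_weighted_mean_ratio_is_one_with_full_coverage(noisy_profile):
    """Weighted by n_xt * (n_ap / n_at), ratios of a complete disjoint
    category system average to exactly 1."""
    _, _, profile = noisy_profile
    for direction in ("up", "down"):
        rows = profile[(profile["direction"] == direction)].dropna(subset=["ratio"])
        rows_all = profile[profile["direction"] == direction]
        # restrict to the case where every category entered the ratio
        if rows_all["n_ap"].iloc[0] == 0:
            continue
        weights = rows_all["n_xt"] * rows_all["n_ap"] / rows_all["n_at"]
        ratios = rows_all.apply(
            lambda r: (r["n_xp"] / r["n_xt"]) / (r["n_ap"] / r["n_at"]), axis=1
        )
        assert float((weights * ratios).sum() / weights.sum()) == pytest.approx(1.0)
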