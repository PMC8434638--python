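"""Paired t-test, BH step-up selection, rank tests and mutual information."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from keydyn import (
    benjamini_hochberg,
    mann_whitney,
    mutual_information,
    paired_t_test,
    wilcoxon_signed_rank,
)
from keydyn.reference import load_reference_pvalues

from .oracles import brute_bh_selected, exact_mannwhitney_p, exact_wilcoxon_p


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t_test([2, 4, 6, 8], [1, 2, 3, 4])  # d = 1,2,3,4
        assert res.statistic == pytest.approx(3.872983, abs=1e-6)
        assert res.p_value == pytest.approx(0.030466, abs=1e-6)
        assert res.n == 4

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = paired_t_test(x, y), paired_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_reference(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=49), rng.normal(size=49)
        res = paired_t_test(x, y)
        ref = ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(size=15)
        perm = rng.permutation(15)
        a, b = paired_t_test(x, y), paired_t_test(x[perm], y[perm])
        assert a.statistic == pytest.approx(b.statistic)


class TestBenjaminiHochberg:
    def test_simple_all_selected(self):
        res = benjamini_hochberg([0.01, 0.02, 0.03], q=0.05)
        assert res.cutoff_rank == 3 and sorted(res.selected) == [0, 1, 2]

    def test_reference_table_selection_counts(self):
        p = load_reference_pvalues()["p_all"]
        assert benjamini_hochberg(p, 0.05).cutoff_rank == 1
        assert benjamini_hochberg(p, 0.12).cutoff_rank == 5
        assert benjamini_hochberg(p, 0.20).cutoff_rank == 12
        (idx,) = benjamini_hochberg(p, 0.05).selected
        assert p.index[idx] == "SPACE" and p.iloc[idx] == 0.0007

    def test_empty_input(self):
        res = benjamini_hochberg([], q=0.05)
        assert res.cutoff_rank == 0 and res.selected.size == 0

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.01, 0.5),
    )
    def test_agrees_with_brute_force_and_is_monotone_in_q(self, p, q):
        res = benjamini_hochberg(p, q)
        assert sorted(res.selected) == brute_bh_selected(p, q)
        wider = benjamini_hochberg(p, min(q + 0.2, 0.99))
        assert set(res.selected) <= set(wider.selected)

    def test_agrees_with_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            q = float(rng.uniform(0.01, 0.4))
            selected = np.zeros(len(p), dtype=bool)
            selected[benjamini_hochberg(p, q).selected] = True
            ref = multipletests(p, alpha=q, method="fdr_bh")[0]
            np.testing.assert_array_equal(selected, ref)


class TestRankTests:
    def test_mann_whitney_separated_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0  # U of the first sample
        assert res.p_value == pytest.approx(0.1)

    def test_mann_whitney_identical_groups(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_mann_whitney_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pooled = rng.permutation(100)[: rng.integers(6, 13)]
            k = len(pooled) // 2
            a, b = pooled[:k].tolist(), pooled[k:].tolist()
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_wilcoxon_one_sided_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.25)

    def test_wilcoxon_antisymmetric(self):
        assert wilcoxon_signed_rank([-1, 2]).p_value == 1.0

    def test_wilcoxon_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            signs = rng.choice([-1, 1], size=rng.integers(5, 11))
            mags = rng.permutation(50)[: len(signs)] + 1
            d = (signs * mags).tolist()
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_wilcoxon_all_zero_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0, 0, 0])


class TestMutualInformation:
    def test_feature_equal_to_label_approaches_entropy(self):
        y = np.array(["A", "B"] * 250)
        x = (y == "A").astype(float)
        mi = mutual_information(x, y, seed=0).values.iloc[0]
        assert mi == pytest.approx(np.log(2), rel=0.10)

    def test_independent_feature_is_near_zero(self):
        rng = np.random.default_rng(7)
        y = np.array(["A", "B"] * 250)
        values = [
            mutual_information(rng.normal(size=500), y, seed=s).values.iloc[0]
            for s in range(100)
        ]
        assert np.mean(values) < 0.02

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="single class"):
            mutual_information(np.ones(10), np.zeros(10))

    def test_nonnegative_and_seeded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 5))
        y = rng.integers(0, 2, size=100)
        a = mutual_information(X, y, seed=3).values
        b = mutual_information(X, y, seed=3).values
        assert (a >= 0).all() and (a == b).all()


def test_paired_feature_evaluation_pairs_within_user_and_topic(small_dataset):
    from keydyn.stats import evaluate_features_paired

    dataset, _ = small_dataset
    res = evaluate_features_paired(dataset.X, dataset.meta)
    assert list(res.index) == list(dataset.X.columns)
    # 2 pairs per user (teacher, subject)
    complete = res["n_pairs"].max()
    assert complete == 2 * dataset.meta["user_id"].nunique()
    assert ((res["p_value"].dropna() >= 0) & (res["p_value"].dropna() <= 1)).all()
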