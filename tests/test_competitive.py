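"""Competitive gene resampling test and the SGSE benchmark."""

import numpy as np
import pytest
from scipy import stats

from rmtgsa.competitive import (
    competitive_pvalue,
    competitive_test,
    sample_random_sets,
    competitive_test_collection,
)
from rmtgsa.containers import GeneSetCollection
from rmtgsa.sgse import sgse_test, weighted_z


class TestSampleRandomSets:
    def test_forced_full_combination(self):
        sets = sample_random_sets(10, 10, 5, seed=0)
        for row in sets:
            assert np.array_equal(np.sort(row), np.arange(10))

    def test_uniform_inclusion_frequency(self):
        sets = sample_random_sets(100, 10, 10_000, seed=1)
        freq = np.bincount(sets.ravel(), minlength=100) / 10_000
        assert freq.min() >= 0.08 and freq.max() <= 0.12  # expectation g/p = 0.1

    def test_distinct_indices_within_draw(self):
        sets = sample_random_sets(20, 8, 500, seed=2)
        assert all(np.unique(row).size == 8 for row in sets)

    def test_deterministic_under_seed(self):
        assert np.array_equal(
            sample_random_sets(50, 5, 100, seed=3), sample_random_sets(50, 5, 100, seed=3)
        )

    def test_g_larger_than_p_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sample_random_sets(5, 6, 10)


class TestCompetitivePvalue:
    def test_strict_exceedance_fraction(self):
        exceed, p = competitive_pvalue(2.5, np.array([1.0, 2.0, 3.0, 4.0]))
        assert (exceed, p) == (2, 0.5)

    def test_zero_attainable_when_observed_dominates(self):
        exceed, p = competitive_pvalue(10.0, np.arange(9.0))
        assert (exceed, p) == (0, 0.0)

    def test_ties_count_as_non_exceedances(self):
        _, p = competitive_pvalue(2.0, np.array([2.0, 2.0, 3.0, 1.0]))
        assert p == 0.25

    def test_plus_one_correction_mode(self):
        _, p = competitive_pvalue(10.0, np.arange(9.0), plus_one=True)
        assert p == pytest.approx(1.0 / 10.0)

    def test_aborts_on_widespread_statistic_failure(self):
        perm = np.ones(100)
        perm[:5] = np.nan
        with pytest.raises(RuntimeError, match="failed"):
            competitive_pvalue(0.5, perm)


class TestCompetitiveTest:
    def test_exhaustive_enumeration_matches_directly_counted_pvalue(self, rng):
        # replace the B draws by all C(6,2)=15 subsets and check Eq-style
        # exceedance counting against a hand enumeration
        from itertools import combinations

        X = rng.standard_normal((12, 6))
        subsets = np.array(list(combinations(range(6), 2)))
        res = competitive_test(X, [0, 1], method="TWT", subsets=subsets)
        from rmtgsa.setstats import twt_statistic

        obs = twt_statistic(X, [0, 1]).statistic
        count = sum(
            twt_statistic(X, list(c)).statistic > obs for c in combinations(range(6), 2)
        )
        assert res.pvalue == pytest.approx(count / 15)
        assert res.perm_count == 15

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((30, 20))
        a = competitive_test(X, np.arange(5), B=50, seed=9)
        b = competitive_test(X, np.arange(5), B=50, seed=9)
        assert a.pvalue == b.pvalue and a.observed_stat == b.observed_stat

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="method"):
            competitive_test(rng.standard_normal((10, 5)), [0, 1], method="GSEA")


class TestCollection:
    def test_results_independent_of_set_order(self, rng):
        X = rng.standard_normal((30, 40))
        sets = {"a": [0, 1, 2], "b": [5, 6, 7], "c": [10, 20, 30]}
        coll = GeneSetCollection.from_index_sets(sets, p=40)
        rev = GeneSetCollection.from_index_sets(dict(reversed(sets.items())), p=40)
        fwd = competitive_test_collection(X, coll, method="MLRT", B=99, seed=4)
        bwd = competitive_test_collection(X, rev, method="MLRT", B=99, seed=4)
        merged = fwd.merge(bwd, on="set_id", suffixes=("_f", "_b"))
        assert np.allclose(merged["pvalue_f"], merged["pvalue_b"])

    def test_schema(self, rng):
        X = rng.standard_normal((20, 12))
        coll = GeneSetCollection.disjoint_blocks(12, 4)
        out = competitive_test_collection(X, coll, B=20, seed=0)
        assert list(out.columns) == ["set_id", "method", "statistic", "B", "pvalue", "seed"]
        assert ((out["pvalue"] >= 0) & (out["pvalue"] <= 1)).all()


class TestSGSE:
    def test_weighted_z_of_uninformative_pvalues(self):
        assert weighted_z(np.full(7, 0.5), np.ones(7)) == pytest.approx(0.5)

    def test_single_pc_reduces_to_its_pvalue(self, rng):
        # rank-one data: exactly one nonzero eigenvalue, so the combined
        # p-value equals the single PC-level Welch t-test p-value
        u = rng.standard_normal(20)
        v = rng.standard_normal(8)
        X = np.outer(u, v)
        res = sgse_test(X, [0, 1, 2])
        c = X - X.mean(axis=0)
        norms = np.linalg.norm(c, axis=0)
        uu, s, _ = np.linalg.svd(c, full_matrices=False)
        corr = (c / norms).T @ uu[:, :1]
        fisher = np.arctanh(np.clip(corr[:, 0], -1 + 1e-12, 1 - 1e-12))
        member = np.zeros(8, bool)
        member[:3] = True
        t = stats.ttest_ind(fisher[member], fisher[~member], equal_var=False)
        z = stats.norm.isf(t.pvalue)
        assert res.pvalue == pytest.approx(float(stats.norm.sf(z)), rel=1e-9)
        assert res.pvalue == pytest.approx(t.pvalue, rel=1e-9)

    def test_requires_two_genes_each_side(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="at least 2 genes"):
            sgse_test(X, [0])
        with pytest.raises(ValueError, match="at least 2 genes"):
            sgse_test(X, [0, 1, 2, 3])
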