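"""Comparator association tests and missing-data handling."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from teqtl import (GenotypeSplit, SimDesign, TimeCourseMatrix, drop_missing,
                   handle_missing, simulate_trait)
from teqtl.association import (ar_test, fisher_test, manova_test,
                               regression_test, static_test, union_test)


def _two_group_trait(a, b):
    """Trait whose column 0 holds the tested values; rest zeros."""
    n = len(a) + len(b)
    vals = np.zeros((n, 6))
    vals[:, 0] = np.concatenate([a, b])
    vals[:, 1:] = np.arange(n)[:, None] + np.arange(5)[None, :]  # filler
    g = np.array([0] * len(a) + [1] * len(b))
    return TimeCourseMatrix(vals), GenotypeSplit.from_genotypes(g)


class TestStatic:
    def test_exact_rank_sum_small_groups(self):
        """p for {1,2,3} vs {10,11,12} equals the enumerated exact value."""
        trait, split = _two_group_trait([1, 2, 3], [10, 11, 12])
        rec = static_test(trait, split, timepoint=0)
        # enumeration oracle: distribution of the rank-sum over all C(6,3)
        pooled = [1, 2, 3, 10, 11, 12]
        ranks = stats.rankdata(pooled)
        observed = ranks[:3].sum()
        sums = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        mu = np.mean(sums)
        p_exact = np.mean([abs(s - mu) >= abs(observed - mu) for s in sums])
        assert rec.p_value == pytest.approx(p_exact)
        assert p_exact == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        trait, split = _two_group_trait([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert static_test(trait, split).p_value == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, linked_trait, split):
        p0 = static_test(linked_trait, split, timepoint=2).p_value
        warped = linked_trait.copy()
        warped.values = np.exp(warped.values / 2) + warped.values ** 3
        p1 = static_test(warped, split, timepoint=2).p_value
        assert p0 == pytest.approx(p1, rel=1e-12)


class TestUnionFisher:
    def test_union_equals_per_timepoint_minimum(self, linked_trait, split):
        rec = union_test(linked_trait, split)
        brute = [static_test(linked_trait, split, timepoint=t).p_value
                 for t in range(linked_trait.n_times)]
        np.testing.assert_allclose(rec.per_timepoint_p, brute, rtol=1e-12)
        assert rec.p_value == pytest.approx(min(brute), rel=1e-12)

    def test_fisher_is_plain_product(self, linked_trait, split):
        rec = fisher_test(linked_trait, split)
        brute = np.array([static_test(linked_trait, split, timepoint=t).p_value
                          for t in range(linked_trait.n_times)])
        assert rec.p_value == pytest.approx(brute.prod(), rel=1e-10)

    def test_fisher_product_ranking_matches_chisq_combination(self, rng):
        """-2 sum(log p) vs chi2_12 orders datasets exactly as the product."""
        scores, chis = [], []
        g = np.tile([0, 1], 15)
        split = GenotypeSplit.from_genotypes(g)
        for _ in range(40):
            design = SimDesign(n_strains=30, effect=("flat", "peak"),
                               effect_scale=float(rng.uniform(0, 0.5)))
            trait = simulate_trait(design, g, seed=rng)
            ps = fisher_test(trait, split).per_timepoint_p
            scores.append(np.prod(ps))
            chis.append(stats.chi2.sf(-2 * np.sum(np.log(ps)), 2 * len(ps)))
        rank = stats.spearmanr(scores, chis).statistic
        assert rank == pytest.approx(1.0, abs=1e-12)

    def test_masked_timepoint_excluded_from_union(self, linked_trait, split):
        masked = linked_trait.copy()
        masked.mask = np.zeros(masked.values.shape, dtype=bool)
        best_t = int(np.argmin(union_test(linked_trait, split).per_timepoint_p))
        masked.mask[:, best_t] = True
        rec = union_test(masked, split)
        assert np.isnan(rec.per_timepoint_p[best_t])
        remaining = np.delete(union_test(linked_trait, split).per_timepoint_p,
                              best_t)
        assert rec.p_value == pytest.approx(np.min(remaining), rel=1e-12)


class TestManova:
    def test_matches_statsmodels_pillai(self, linked_trait, split):
        sm = pytest.importorskip("statsmodels.multivariate.manova")
        import pandas as pd
        rec = manova_test(linked_trait, split)
        df = pd.DataFrame(linked_trait.values,
                          columns=[f"t{i}" for i in range(6)])
        df["g"] = split.indicator(linked_trait.n_strains)
        res = sm.MANOVA.from_formula(
            "t0+t1+t2+t3+t4+t5 ~ g", data=df).mv_test().results["g"]["stat"]
        assert rec.p_value == pytest.approx(
            float(res.loc["Pillai's trace", "Pr > F"]), rel=1e-8)

    def test_single_timepoint_collapses_to_anova(self, rng):
        vals = rng.standard_normal((30, 1)) + np.repeat([0.0, 1.0], 15)[:, None]
        trait = TimeCourseMatrix(vals)
        split = GenotypeSplit.from_genotypes(np.repeat([0, 1], 15))
        rec = manova_test(trait, split)
        f, p = stats.f_oneway(vals[:15, 0], vals[15:, 0])
        assert rec.p_value == pytest.approx(p, rel=1e-10)

    def test_too_few_strains_rejected(self):
        trait = TimeCourseMatrix(np.random.default_rng(0).standard_normal((7, 6)))
        split = GenotypeSplit.from_genotypes(np.array([0, 0, 0, 1, 1, 1, 1]))
        with pytest.raises(ValueError):
            manova_test(trait, split)


class TestRegression:
    def test_full_rss_is_sum_of_per_group_fits(self, linked_trait, split):
        rec = regression_test(linked_trait, split)
        t = linked_trait.times
        P = np.vander(t, 4, increasing=True)
        total = 0.0
        for idx in split.groups:
            y = linked_trait.values[idx].ravel()
            X = np.tile(P, (len(idx), 1))
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            total += float(((y - X @ coef) ** 2).sum())
        assert rec.extra["rss1"] == pytest.approx(total, rel=1e-10)

    def test_distinct_noiseless_cubics_hit_machine_floor(self):
        t = np.arange(1, 7, dtype=float)
        c0 = 1.0 + 0.5 * t
        c1 = -1.0 + 0.1 * t ** 2
        vals = np.vstack([np.tile(c0, (5, 1)), np.tile(c1, (5, 1))])
        trait = TimeCourseMatrix(vals)
        split = GenotypeSplit.from_genotypes(np.repeat([0, 1], 5))
        assert regression_test(trait, split).p_value < 1e-100

    def test_null_pvalues_roughly_uniform(self, rng):
        """Shared cubic + iid noise: F p-values are U(0,1)."""
        ps = []
        g = np.tile([0, 1], 10)
        split = GenotypeSplit.from_genotypes(g)
        t = np.arange(1, 7, dtype=float)
        curve = 0.3 * t - 0.05 * t ** 2
        for _ in range(200):
            vals = curve + rng.standard_normal((20, 6)) * 0.5
            ps.append(regression_test(TimeCourseMatrix(vals), split).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAR:
    def test_intercept_shift_detected(self, rng):
        g = np.tile([0, 1], 40)
        vals = np.zeros((80, 6))
        vals[:, 0] = rng.standard_normal(80) + 2.0 * g
        for t in range(1, 6):
            vals[:, t] = 2.0 * g + 0.5 * vals[:, t - 1] + \
                0.3 * rng.standard_normal(80)
        rec = ar_test(TimeCourseMatrix(vals), GenotypeSplit.from_genotypes(g))
        assert rec.p_value < 1e-6

    def test_null_uniform(self, rng):
        ps = []
        split = GenotypeSplit.from_genotypes(np.tile([0, 1], 15))
        for _ in range(200):
            vals = rng.standard_normal((30, 6))
            ps.append(ar_test(TimeCourseMatrix(vals), split).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_minimal_two_timepoints(self, rng):
        vals = rng.standard_normal((20, 2))
        rec = ar_test(TimeCourseMatrix(vals),
                      GenotypeSplit.from_genotypes(np.tile([0, 1], 10)))
        assert 0 <= rec.p_value <= 1


class TestHandleMissing:
    def test_no_mask_is_identity(self, linked_trait, split):
        assert handle_missing(linked_trait, split, "mptga") is linked_trait

    def test_noiseless_cubic_imputed_exactly(self):
        t = np.arange(1, 7, dtype=float)
        curve0 = 1.0 - 0.2 * t + 0.03 * t ** 3
        curve1 = -0.5 + 0.4 * t
        vals = np.vstack([np.tile(curve0, (10, 1)), np.tile(curve1, (10, 1))])
        trait = TimeCourseMatrix(vals)
        trait.mask = np.zeros(vals.shape, dtype=bool)
        trait.mask[0, 3] = True
        trait.mask[12, 5] = True
        split = GenotypeSplit.from_genotypes(np.repeat([0, 1], 10))
        out = handle_missing(trait, split, "regression")
        assert out.mask is None
        assert out.values[0, 3] == pytest.approx(curve0[3], abs=1e-8)
        assert out.values[12, 5] == pytest.approx(curve1[5], abs=1e-8)

    def test_mask_only_methods_drop_incomplete_strains(self, linked_trait, split):
        masked = drop_missing(linked_trait, 0.08, seed=3)
        out = handle_missing(masked, split, "union")
        incomplete = ~masked.complete_rows()
        assert out.mask[incomplete].all()
        complete = masked.complete_rows()
        assert not out.mask[complete].any()

    def test_no_complete_strains_raises(self, linked_trait, split):
        masked = linked_trait.copy()
        masked.mask = np.ones(masked.values.shape, dtype=bool)
        with pytest.raises(ValueError, match="complete"):
            handle_missing(masked, split, "mptga")
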