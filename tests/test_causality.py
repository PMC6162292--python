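"""TGCT: model fitting, directional calls, BIC selection, regulator ranking."""

import numpy as np
import pytest

from teqtl import (CausalPairDesign, GenotypeSplit, TimeCourseMatrix,
                   compare_m1_m2, fit_tgct_models, rank_regulators,
                   select_cis_trans_model, simulate_pair)
from teqtl.association import ar_test
from teqtl.causality import FilterNotSatisfied, K_Y


def _pair(model="causal", n=100, seed=0, **kw):
    design = CausalPairDesign(model=model, n_strains=n, **kw)
    g = np.tile([0, 1], n // 2)
    X, Y = simulate_pair(design, g, seed=seed)
    return X, Y, GenotypeSplit.from_genotypes(g)


class TestFits:
    def test_toy_ols_and_bic_match_independent_computation(self):
        """Coefficients, RSS, loglik and BIC agree with statsmodels OLS
        plus direct evaluation of the profile-likelihood formula."""
        sm_api = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        X = TimeCourseMatrix(rng.standard_normal((4, 3)), gene_id="x")
        Y = TimeCourseMatrix(rng.standard_normal((4, 3)), gene_id="y")
        split = GenotypeSplit.from_genotypes(np.array([0, 0, 1, 1]))
        fits = {f.model_id: f for f in fit_tgct_models(X, Y, split)}

        y = Y.values[:, 1:].ravel()
        ylag = Y.values[:, :-1].ravel()
        xlag = X.values[:, :-1].ravel()
        D = np.column_stack([np.ones(8), ylag, xlag])
        res = sm_api.OLS(y, D).fit()
        f1 = fits["M1"]
        np.testing.assert_allclose(f1.coef_y, res.params, rtol=1e-8)
        assert f1.rss_y == pytest.approx(float(res.ssr), rel=1e-8)
        n_obs = 8
        ll = (-n_obs / 2 * np.log(2 * np.pi) - n_obs / 2 * np.log(res.ssr)
              + n_obs / 2 * np.log(n_obs) - n_obs / 2)
        assert f1.loglik_y == pytest.approx(ll, rel=1e-10)
        assert f1.bic == pytest.approx(np.log(n_obs) * 3 - 2 * ll, rel=1e-10)

    def test_bic_formula_identity(self):
        X, Y, split = _pair(seed=2)
        for f in fit_tgct_models(X, Y, split):
            assert f.bic == pytest.approx(
                np.log(X.n_strains * (X.n_times - 1)) * f.k - 2 * f.loglik_y,
                rel=1e-12)
            assert f.k == K_Y[f.model_id]

    def test_m3_equation_matches_ar_test_full_model(self):
        """The independent-model Y equation is the AR association full fit."""
        X, Y, split = _pair(model="independent", seed=3)
        f3 = [f for f in fit_tgct_models(X, Y, split, models=("M3",))][0]
        rec = ar_test(Y, split)
        assert f3.rss_y == pytest.approx(rec.extra["rss1"], rel=1e-10)

    def test_nested_rss_ordering(self):
        """Adding the lagged-X term can only reduce the residual sum."""
        for seed in range(5):
            X, Y, split = _pair(model="partial", seed=seed)
            fits = {f.model_id: f for f in fit_tgct_models(X, Y, split)}
            assert fits["M4"].rss_y <= fits["M3"].rss_y + 1e-9

    def test_constant_trait_rejected(self):
        X = TimeCourseMatrix(np.ones((6, 4)))
        Y = TimeCourseMatrix(np.ones((6, 4)))
        split = GenotypeSplit.from_genotypes(np.tile([0, 1], 3))
        with pytest.raises(ValueError, match="rank"):
            fit_tgct_models(X, Y, split)


class TestDirection:
    def test_lag_copy_pair_called_causal(self):
        X, Y, split = _pair(beta0=(0, 0), beta1=(0, 0), beta2=1.0,
                            y_noise_sd=0.05, seed=4)
        call = compare_m1_m2(X, Y, split)
        assert call.best_model == "M1"
        assert call.log_lr > 0

    def test_antisymmetric_under_swap(self):
        X, Y, split = _pair(seed=5)
        fwd = compare_m1_m2(X, Y, split)
        rev = compare_m1_m2(Y, X, split)
        assert fwd.log_lr == pytest.approx(-rev.log_lr, rel=1e-10)
        assert {fwd.best_model, rev.best_model} <= {"M1", "M2"}
        assert (fwd.best_model == "M1") == (rev.best_model == "M2")

    def test_symmetric_null_is_a_coin_flip(self):
        """Pure-noise pairs with no genetics split calls ~50/50."""
        rng = np.random.default_rng(6)
        split = GenotypeSplit.from_genotypes(np.tile([0, 1], 25))
        calls = []
        for _ in range(200):
            X = TimeCourseMatrix(rng.standard_normal((50, 6)))
            Y = TimeCourseMatrix(rng.standard_normal((50, 6)))
            calls.append(compare_m1_m2(X, Y, split).best_model == "M1")
        assert 0.4 < np.mean(calls) < 0.6

    def test_filter_enforced(self):
        X, Y, split = _pair(seed=7)
        with pytest.raises(FilterNotSatisfied):
            compare_m1_m2(X, Y, split, p_x=1e-3, p_y=1e-9)


class TestSelection:
    def test_degenerate_partial_reduces_to_independent(self):
        """Partial-model data with beta2 = 0 selects the independent model."""
        hits = 0
        for seed in range(60):
            X, Y, split = _pair(model="partial", n=150, beta0=(0.0, 1.0),
                                beta1=(0.4, 0.4), beta2=0.0, seed=seed)
            hits += select_cis_trans_model(X, Y, split).best_model == "M3"
        assert hits >= 54  # >= 90%

    def test_degenerate_partial_reduces_to_causal(self):
        """Equal per-genotype Y coefficients collapse the partial model."""
        hits = 0
        for seed in range(60):
            X, Y, split = _pair(model="partial", n=150, beta0=(0.0, 0.0),
                                beta1=(0.5, 0.5), beta2=0.8, seed=seed)
            hits += select_cis_trans_model(X, Y, split).best_model == "M1"
        assert hits >= 54

    def test_bic_margin_nonnegative_and_tiebreak_simple(self):
        X, Y, split = _pair(seed=8)
        call = select_cis_trans_model(X, Y, split)
        assert call.bic_margin >= 0
        assert call.best_model in ("M1", "M3", "M4")


class TestRegulatorRanking:
    def _hotspot_calls(self, seed=9):
        """One real driver with 10 targets, two decoy cis genes."""
        rng = np.random.default_rng(seed)
        g = np.tile([0, 1], 50)
        split = GenotypeSplit.from_genotypes(g)
        driver_design = CausalPairDesign(model="causal", n_strains=100,
                                         beta1=(0.5, 0.5), beta2=0.9)
        calls = []
        for driver in ("cis_driver", "cis_decoy1", "cis_decoy2"):
            for k in range(10):
                X, Y = simulate_pair(driver_design, g, seed=rng)
                X.gene_id = driver
                Y.gene_id = f"trans{k}"
                if driver != "cis_driver":
                    # decoys: independent trans traits with own genetics
                    d2 = CausalPairDesign(model="independent", n_strains=100,
                                          beta0=(0.0, 1.0), beta1=(0.5, 0.5))
                    _, Y = simulate_pair(d2, g, seed=rng)
                    Y.gene_id = f"trans{k}"
                calls.append(select_cis_trans_model(X, Y, split))
        return calls

    def test_driver_ranked_first(self):
        ranking = rank_regulators(self._hotspot_calls(), hotspot_cutoff=8)
        assert ranking.iloc[0]["x_gene"] == "cis_driver"
        assert ranking.iloc[0]["n_causal"] >= 8
        assert bool(ranking.iloc[0]["is_key_regulator"])

    def test_empty_calls_empty_ranking(self):
        assert rank_regulators([], hotspot_cutoff=5).empty

    def test_duplicated_driver_ties_are_both_reported(self):
        calls = self._hotspot_calls()
        dup = [c for c in calls if c.x_gene == "cis_driver"]
        import copy
        twins = []
        for c in dup:
            t = copy.copy(c)
            t.x_gene = "cis_twin"
            twins.append(t)
        ranking = rank_regulators(calls + twins, hotspot_cutoff=8)
        top2 = set(ranking.iloc[:2]["x_gene"])
        assert top2 == {"cis_driver", "cis_twin"}
        assert ranking.iloc[0]["n_causal"] == ranking.iloc[1]["n_causal"]
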