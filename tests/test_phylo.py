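"""Covariance structures, model fitting, ancestral states, PGLS."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from zdnaevo import (DataError, EvoModelFit, Phylogeny, adjust_trait,
                     ancestral_states_bm, bm_covariance, correlation_call,
                     fit_continuous, model_covariance, pgls_bootstrap,
                     pgls_fit, prune_to_common, select_model, sim_trait,
                     sim_regression_dataset, sim_yule_tree)

from _oracles import ancestral_states_joint_gls, bm_covariance_dendropy


@pytest.fixture(scope="module")
def yule20():
    return Phylogeny.from_newick(sim_yule_tree(20, 1.0, seed=42))


def star_tree(n, depth=1.0):
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return Phylogeny.from_newick(f"({tips});")


class TestPhylogeny:
    def test_negative_branch_length_rejected(self):
        with pytest.raises(DataError, match="negative"):
            Phylogeny.from_newick("((A:1,B:-0.5):1,C:2);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(DataError):
            Phylogeny.from_newick("((A:1,A:1):1,C:2);")

    def test_ultrametricity_detection(self):
        assert Phylogeny.from_newick("((A:1,B:1):1,C:2);").is_ultrametric()
        assert not Phylogeny.from_newick("((A:1,B:2):1,C:2);").is_ultrametric()


class TestCovariances:
    def test_two_tip_identity(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        assert np.allclose(bm_covariance(t), np.eye(2))

    def test_three_tip_hand_example(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C = bm_covariance(t)
        labels = t.tip_labels
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["A"], i["A"]] == pytest.approx(2)
        assert C[i["B"], i["B"]] == pytest.approx(2)
        assert C[i["C"], i["C"]] == pytest.approx(2)
        assert C[i["A"], i["B"]] == pytest.approx(1)
        assert C[i["A"], i["C"]] == pytest.approx(0)
        assert C[i["B"], i["C"]] == pytest.approx(0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_match_pairwise_oracle(self, seed):
        phy = Phylogeny.from_newick(sim_yule_tree(12, 1.0, seed=seed))
        assert np.allclose(bm_covariance(phy), bm_covariance_dendropy(phy),
                           atol=1e-10)

    def test_lambda_transforms(self, yule20):
        C = bm_covariance(yule20)
        assert np.allclose(model_covariance(yule20, "lambda", 1.0), C)
        V0 = model_covariance(yule20, "lambda", 0.0)
        assert np.allclose(V0, np.diag(np.diag(C)))

    def test_ou_small_alpha_limit(self, yule20):
        C = bm_covariance(yule20)
        V = model_covariance(yule20, "OU", 1e-8)
        assert np.max(np.abs(V - C)) < 1e-5

    def test_eb_zero_rate_limit(self, yule20):
        C = bm_covariance(yule20)
        assert np.allclose(model_covariance(yule20, "EB", 0.0), C)
        # small negative r approaches C too
        V = model_covariance(yule20, "EB", -1e-9)
        assert np.max(np.abs(V - C)) < 1e-5

    @pytest.mark.parametrize("model,bad", [
        ("lambda", -0.1), ("lambda", 1.5), ("OU", 0.0), ("OU", -1.0),
        ("EB", 0.5)])
    def test_out_of_bounds_shape_rejected(self, yule20, model, bad):
        with pytest.raises(DataError):
            model_covariance(yule20, model, bad)

    def test_ou_requires_ultrametric(self):
        t = Phylogeny.from_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(DataError, match="ultrametric"):
            model_covariance(t, "OU", 1.0)


class TestFitContinuous:
    def test_two_tip_bm_closed_form(self):
        t = Phylogeny.from_newick("(A:2.0,B:2.0);")
        x = {"A": 1.0, "B": 3.0}
        fit = fit_continuous(t, x, "BM")
        mu = 2.0
        sigma2 = ((1 - mu) ** 2 + (3 - mu) ** 2) / (2 * 2.0)
        assert fit.root_state == pytest.approx(mu, abs=1e-8)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-8)

    def test_constant_trait_flagged_degenerate(self, yule20):
        fit = fit_continuous(yule20, np.full(20, 3.14), "BM")
        assert fit.degenerate and fit.sigma2 == 0.0
        assert fit.logLik == math.inf

    def test_aicc_formula(self):
        # AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)
        from zdnaevo.phylo import _aicc
        assert _aicc(-10.0, 2, 20) == pytest.approx(20 + 4 + 12 / 17)

    def test_loglik_matches_dense_mvn(self, yule20):
        x = sim_trait(yule20, "BM", seed=3)
        for model in ("BM", "OU", "EB", "lambda"):
            fit = fit_continuous(yule20, x, model)
            V = fit.sigma2 * model_covariance(yule20, fit.model,
                                              fit.shape_param)
            ref = sstats.multivariate_normal.logpdf(
                x.to_numpy(), mean=np.full(20, fit.root_state), cov=V)
            assert fit.logLik == pytest.approx(ref, abs=1e-6)

    def test_lambda_nests_bm(self, yule20):
        for seed in range(5):
            x = sim_trait(yule20, "BM", seed=seed)
            f_bm = fit_continuous(yule20, x, "BM")
            f_lam = fit_continuous(yule20, x, "lambda")
            assert f_lam.logLik >= f_bm.logLik - 1e-6

    def test_missing_tip_label_errors(self, yule20):
        with pytest.raises(DataError, match="missing"):
            fit_continuous(yule20, {"T1": 1.0}, "BM")


class TestSelectModel:
    def fake(self, model, aicc, k, key=("d",)):
        return EvoModelFit(model=model, sigma2=1, root_state=0,
                           shape_param=None, logLik=0, k_params=k, AICc=aicc,
                           n=10, data_key=key)

    def test_minimum_aicc_wins(self):
        assert select_model([self.fake("BM", 100, 2),
                             self.fake("OU", 95, 3)]).model == "OU"

    def test_exact_tie_prefers_fewer_parameters(self):
        assert select_model([self.fake("lambda", 50, 3),
                             self.fake("BM", 50, 2)]).model == "BM"

    def test_mismatched_data_rejected(self):
        with pytest.raises(DataError):
            select_model([self.fake("BM", 1, 2, key=("a",)),
                          self.fake("OU", 2, 3, key=("b",))])


class TestAncestralStates:
    def test_constant_trait_gives_constant_states(self, yule20):
        anc = ancestral_states_bm(yule20, np.full(20, 7.5))
        assert np.allclose(anc.to_numpy(), 7.5)

    def test_two_tip_inverse_variance_weighting(self):
        t1, t2 = 1.0, 3.0
        t = Phylogeny.from_newick(f"(A:{t1},B:{t2});")
        xa, xb = 2.0, 6.0
        anc = ancestral_states_bm(t, {"A": xa, "B": xb})
        expected = (xa / t1 + xb / t2) / (1 / t1 + 1 / t2)
        assert anc.iloc[0] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_joint_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        phy = Phylogeny.from_newick(sim_yule_tree(n, 1.0, seed=seed + 500))
        x = sim_trait(phy, "BM", seed=seed + 900).to_numpy()
        mine = ancestral_states_bm(phy, x).to_numpy()
        oracle = ancestral_states_joint_gls(phy, x)
        assert np.allclose(mine, oracle, atol=1e-8)


class TestPgls:
    def ols_reference(self, y, x):
        import statsmodels.api as sm
        X = sm.add_constant(x)
        return sm.OLS(y, X).fit()

    def test_star_tree_equals_ols(self):
        phy = star_tree(30, depth=2.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1.0 + 0.8 * x + rng.normal(size=30)
        X = np.column_stack([np.ones(30), x])
        fit = pgls_fit(phy, y, X, model="BM")
        ref = self.ols_reference(y, x)
        assert np.allclose(fit.coef, ref.params, atol=1e-8)
        assert np.allclose(fit.se, ref.bse, atol=1e-8)
        assert np.allclose(fit.pvalues, ref.pvalues, atol=1e-8)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-8)

    def test_lambda_zero_equals_ols_on_any_tree(self, yule20):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.3 * x + rng.normal(size=20)
        X = np.column_stack([np.ones(20), x])
        fit = pgls_fit(yule20, y, X, model="lambda", fixed_shape=0.0)
        ref = self.ols_reference(y, x)
        assert np.allclose(fit.coef, ref.params, atol=1e-8)
        assert np.allclose(fit.pvalues, ref.pvalues, atol=1e-8)

    def test_slope_recovery_loose(self):
        # scaled sanity check; the full calibration lives in the
        # acceptance suite
        slopes = []
        for seed in range(20):
            phy = Phylogeny.from_newick(sim_yule_tree(60, 1.0, seed=seed))
            xs = sim_trait(phy, "BM", seed=1000 + seed)
            _, ys = sim_regression_dataset(phy, xs, (0.0, 0.5), "BM",
                                           seed=2000 + seed, sigma2=0.25)
            X = np.column_stack([np.ones(60), xs.to_numpy()])
            slopes.append(pgls_fit(phy, ys, X, model="BM").coef[1])
        assert abs(np.mean(slopes) - 0.5) < 0.1

    def test_rank_deficient_design_rejected(self, yule20):
        X = np.ones((20, 2))
        with pytest.raises(DataError):
            pgls_fit(yule20, np.arange(20.0), X)

    def test_too_few_species_rejected(self):
        phy = star_tree(3)
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        with pytest.raises(DataError, match="too few"):
            pgls_fit(phy, np.arange(3.0), X)

    def test_model_selection_reports_best_aicc(self, yule20):
        xs = sim_trait(yule20, "BM", seed=5)
        _, ys = sim_regression_dataset(yule20, xs, (0.0, 1.0), "BM",
                                       seed=6, sigma2=0.5)
        X = np.column_stack([np.ones(20), xs.to_numpy()])
        full = pgls_fit(yule20, ys, X)
        singles = {m: pgls_fit(yule20, ys, X, model=m)
                   for m in ("BM", "OU", "lambda")}
        assert full.AICc == pytest.approx(
            min(s.AICc for s in singles.values()))
        assert full.model == min(singles, key=lambda m: singles[m].AICc)


class TestBootstrap:
    def test_same_seed_reproducible(self, yule20):
        xs = sim_trait(yule20, "BM", seed=8)
        _, ys = sim_regression_dataset(yule20, xs, (0.0, 0.5), "BM", seed=9)
        X = np.column_stack([np.ones(20), xs.to_numpy()])
        fit = pgls_fit(yule20, ys, X, model="BM")
        b1 = pgls_bootstrap(fit, yule20, ys, X, B=25, seed=123)
        b2 = pgls_bootstrap(fit, yule20, ys, X, B=25, seed=123)
        assert np.array_equal(b1["replicates"], b2["replicates"])
        b3 = pgls_bootstrap(fit, yule20, ys, X, B=25, seed=124)
        assert not np.array_equal(b1["replicates"], b3["replicates"])

    def test_quantiles_ordered_and_b_validated(self, yule20):
        xs = sim_trait(yule20, "BM", seed=10)
        _, ys = sim_regression_dataset(yule20, xs, (0.0, 0.5), "BM", seed=11)
        X = np.column_stack([np.ones(20), xs.to_numpy()])
        fit = pgls_fit(yule20, ys, X, model="BM")
        b = pgls_bootstrap(fit, yule20, ys, X, B=50, seed=0)
        q = b["quantiles"]
        assert q["2.5%"] <= q["50%"] <= q["97.5%"]
        with pytest.raises(DataError):
            pgls_bootstrap(fit, yule20, ys, X, B=1)


class TestCorrelationCall:
    @pytest.mark.parametrize("p,r2,expected", [
        (0.01, 0.20, True),
        (0.01, 0.05, False),
        (0.20, 0.30, False),
        (0.049999, 0.100001, True),
        (0.05, 0.2, False),
    ])
    def test_rule(self, p, r2, expected):
        assert correlation_call(p, r2) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            correlation_call(float("nan"), 0.2)


class TestAdjustTrait:
    def test_constant_mass_gives_centered_logs(self):
        d = np.array([10.0, 100.0, 1000.0])
        m = np.full(3, 50.0)
        adj = adjust_trait(d, m)
        ld = np.log10(d)
        assert np.allclose(adj, ld - ld.mean(), atol=1e-10)

    def test_perfect_allometry_gives_zero_residuals(self):
        m = np.array([1.0, 10.0, 100.0, 1000.0])
        d = 3.0 * m ** 0.75
        assert np.allclose(adjust_trait(d, m), 0.0, atol=1e-10)

    def test_five_species_hand_example(self):
        m = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        d = np.array([12.0, 15.0, 21.0, 26.0, 40.0])
        import statsmodels.api as sm
        ref = sm.OLS(np.log10(d), sm.add_constant(np.log10(m))).fit().resid
        assert np.allclose(adjust_trait(d, m), ref, atol=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            adjust_trait([1.0, -2.0], [1.0, 1.0])


class TestPrune:
    def test_prune_preserves_surviving_depths(self):
        phy = Phylogeny.from_newick(sim_yule_tree(5, 1.0, seed=77))
        depths = dict(zip(phy.tip_labels, phy.depths))
        keep = phy.tip_labels[:3]
        table = pd.DataFrame({"species": keep, "trait": [1.0, 2.0, 3.0]})
        pruned, aligned = prune_to_common(phy, table)
        assert sorted(pruned.tip_labels) == sorted(keep)
        for lab, depth in zip(pruned.tip_labels, pruned.depths):
            assert depth == pytest.approx(depths[lab], abs=1e-9)
        assert list(aligned.index) == pruned.tip_labels

    def test_full_overlap_is_identity(self):
        phy = Phylogeny.from_newick(sim_yule_tree(6, 1.0, seed=78))
        table = pd.DataFrame({"species": phy.tip_labels,
                              "trait": np.arange(6.0)})
        pruned, aligned = prune_to_common(phy, table)
        assert pruned is phy
        assert list(aligned.index) == phy.tip_labels

    def test_nan_rows_dropped(self):
        phy = Phylogeny.from_newick(sim_yule_tree(6, 1.0, seed=79))
        vals = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        table = pd.DataFrame({"species": phy.tip_labels, "trait": vals})
        pruned, aligned = prune_to_common(phy, table)
        assert pruned.n == 5
        assert not aligned["trait"].isna().any()

    def test_disjoint_species_rejected(self):
        phy = Phylogeny.from_newick(sim_yule_tree(5, 1.0, seed=80))
        table = pd.DataFrame({"species": ["x", "y", "z"],
                              "trait": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError, match="fewer than 3"):
            prune_to_common(phy, table)

    def test_duplicate_rows_rejected(self):
        phy = Phylogeny.from_newick(sim_yule_tree(5, 1.0, seed=81))
        sp = phy.tip_labels[0]
        table = pd.DataFrame({"species": [sp, sp, phy.tip_labels[1],
                                          phy.tip_labels[2]],
                              "trait": [1.0, 1.0, 2.0, 3.0]})
        with pytest.raises(DataError, match="duplicate"):
            prune_to_common(phy, table)
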