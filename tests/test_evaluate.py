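import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gweis import (
    SimConfig,
    fdr_adjust,
    fit_comparison,
    improvement_report,
    incremental_r2,
    permutation_empirical_p,
    run_gwas,
    run_gweis,
    simulate_covariates,
    simulate_exposure,
    simulate_genotypes,
    simulate_phenotype,
)
from gweis.evaluate import ModelComparison
from gweis.pipeline import joint_vs_combined, split_panel
from gweis.prs import PrsScorer


def _gaussian_loglik(y, X):
    """Brute-force profile log-likelihood of an OLS fit (MLE variance)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = resid @ resid / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


class TestFitComparison:
    def test_identical_term_sets_give_zero_lrt(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        terms = pd.DataFrame({"PRS": rng.standard_normal(100)})
        comp = fit_comparison(y, terms, terms)
        assert comp.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert comp.lrt_p == 1.0
        assert comp.incremental_r2 == pytest.approx(0.0, abs=1e-12)

    def test_lrt_matches_loglik_oracle_on_hand_dataset(self):
        y = np.array([2.1, 1.3, 3.3, 0.2, 4.9, 2.2, 1.1, 3.8, 2.7, 0.9, 4.1, 3.0])
        x1 = np.array([1.0, 0, 2, 0, 3, 1, 0, 2, 2, 1, 3, 2])
        x2 = np.array([0.4, 1.1, -0.2, 0.9, 0.1, -1.3, 0.5, 0.2, -0.8, 1.7, 0.3, -0.1])
        comp = fit_comparison(
            y, pd.DataFrame({"x1": x1}), pd.DataFrame({"x1": x1, "x2": x2})
        )
        n = len(y)
        ll_null = _gaussian_loglik(y, np.column_stack([np.ones(n), x1]))
        ll_full = _gaussian_loglik(y, np.column_stack([np.ones(n), x1, x2]))
        assert comp.lrt_stat == pytest.approx(2 * (ll_full - ll_null), rel=1e-8)
        assert comp.lrt_df == 1

    def test_r2_is_net_of_covariates(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(300)
        prs = rng.standard_normal(300)
        y = 1.0 * c + 0.5 * prs + rng.standard_normal(300)
        comp = fit_comparison(
            y, None, pd.DataFrame({"PRS": prs}), covariates=pd.DataFrame({"c": c})
        )
        # R2 attributable to the PRS, not to the strong covariate
        assert 0.05 < comp.r2_full < 0.35

    def test_nested_f_and_lrt_order_agree(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(80)
        lrt_stats, f_ps = [], []
        for slope in (0.0, 0.3, 0.8):
            x = rng.standard_normal(80)
            yy = y + slope * x
            comp = fit_comparison(yy, None, pd.DataFrame({"x": x}))
            X0, X1 = np.ones((80, 1)), np.column_stack([np.ones(80), x])
            rss0 = ((yy - X0 @ np.linalg.lstsq(X0, yy, rcond=None)[0]) ** 2).sum()
            rss1 = ((yy - X1 @ np.linalg.lstsq(X1, yy, rcond=None)[0]) ** 2).sum()
            f = (rss0 - rss1) / (rss1 / (80 - 2))
            lrt_stats.append(comp.lrt_stat)
            f_ps.append(stats.f.sf(f, 1, 78))
        assert np.argsort(lrt_stats).tolist() == np.argsort(f_ps)[::-1].tolist()

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(50)
        a = pd.DataFrame({"a": rng.standard_normal(50)})
        b = pd.DataFrame({"b": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="nest"):
            fit_comparison(y, a, b)

    def test_span_nesting_accepts_linear_constraint(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(60)
        g = rng.standard_normal(60)
        y = d + 0.5 * g + rng.standard_normal(60)
        comp = fit_comparison(
            y,
            pd.DataFrame({"joint": d + g}),
            pd.DataFrame({"d": d, "g": g}),
        )
        assert comp.lrt_df == 1 and comp.r2_full >= comp.r2_null

    def test_binomial_nagelkerke_r2(self):
        rng = np.random.default_rng(5)
        prs = rng.standard_normal(400)
        p = 1 / (1 + np.exp(-(0.8 * prs)))
        y = rng.binomial(1, p)
        comp = fit_comparison(y, None, pd.DataFrame({"PRS": prs}), family="binomial")
        assert 0.0 < comp.r2_full < 1.0
        assert comp.lrt_p < 1e-6

    def test_incremental_prediction_with_true_gxe(self):
        """Adding the GxE-weighted score to the additive score helps when
        the trait truly contains interaction effects."""
        wins = 0
        for rep in range(5):
            cfg = SimConfig(
                n_samples=5000, n_snps=300, n_causal_additive=30, n_causal_gxe=10,
                var_additive=0.10, var_gxe=0.12, seed=230 + rep,
            )
            panel = simulate_genotypes(cfg)
            expo = simulate_exposure(panel, cfg)
            cov = simulate_covariates(cfg)
            truth = simulate_phenotype(panel, expo.counts, cov, cfg)
            disc, targ = split_panel(panel, 2500)
            gwas = run_gwas(disc, truth.y[:2500], cov.iloc[:2500])
            gweis = run_gweis(disc, truth.y[:2500], expo.counts[:2500], cov.iloc[:2500])
            prs_d = (
                PrsScorer("additive", p_threshold=0.05).fit(gwas).transform(targ)["SCORE"].to_numpy()
            )
            prs_gxe = (
                PrsScorer("gxe", p_threshold=0.05).fit(gweis).transform(targ)["SCORE"].to_numpy()
            )
            comp = fit_comparison(
                truth.y[2500:],
                pd.DataFrame({"PRS_D": prs_d}),
                pd.DataFrame({"PRS_D": prs_d, "PRS_GxE": prs_gxe}),
                covariates=cov.iloc[2500:].reset_index(drop=True),
            )
            wins += comp.incremental_r2 > 0 and comp.lrt_p < 0.05
        assert wins >= 3  # gain detected in a majority of replicates


class TestPermutation:
    def test_floor_at_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(200)
        ep = permutation_empirical_p(y, y, n_perm=1000, seed=1)
        assert ep == pytest.approx(1 / 1001)

    def test_null_prs_calibration(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(150)
        eps = [
            permutation_empirical_p(y, rng.standard_normal(150), n_perm=150, seed=s)
            for s in range(30)
        ]
        assert abs(np.mean(eps) - 0.5) < 0.15

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(120)
        prs = 0.2 * y + rng.standard_normal(120)
        a = permutation_empirical_p(y, prs, n_perm=300, seed=9)
        b = permutation_empirical_p(y, prs, n_perm=300, seed=9)
        assert a == b

    def test_rank_invariance_under_monotone_phenotype_rescale(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(100)
        prs = rng.standard_normal(100)
        a = permutation_empirical_p(2.0 * y + 5.0, prs, n_perm=200, seed=3)
        b = permutation_empirical_p(y, prs, n_perm=200, seed=3)
        assert a == b

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            permutation_empirical_p(np.ones(150), np.arange(150.0), n_perm=100)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_empirical_p(np.arange(150.0), np.arange(150.0), n_perm=50)


class TestFdr:
    def test_single_pvalue_unchanged(self):
        assert fdr_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_adjusted_at_least_raw(self):
        p = np.random.default_rng(11).uniform(size=50)
        assert (fdr_adjust(p) >= p - 1e-15).all()

    def test_matches_brute_force_step_up(self):
        p = np.random.default_rng(12).uniform(size=15)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):  # step-up from the largest p
            running = min(running, p[order[rank - 1]] * m / rank)
            adj[order[rank - 1]] = running
        np.testing.assert_allclose(fdr_adjust(p), adj, rtol=1e-12)

    def test_controls_fdr_with_known_nulls(self):
        rng = np.random.default_rng(13)
        fdps = []
        for _ in range(40):
            null_p = rng.uniform(size=160)
            alt_p = rng.beta(0.05, 10.0, size=40)  # strongly non-null
            p = np.concatenate([null_p, alt_p])
            rejected = fdr_adjust(p) <= 0.05
            n_rej = rejected.sum()
            fdps.append(rejected[:160].sum() / n_rej if n_rej else 0.0)
        assert np.mean(fdps) <= 0.06

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_adjust([])


class TestImprovementReport:
    def _comp(self, trait, r2_null, r2_full, lrt_p=0.01):
        return ModelComparison(
            trait_id=trait, terms_null=["PRS_D"], terms_full=["PRS_D", "PRS_GxE"],
            r2_null=r2_null, r2_full=r2_full, incremental_r2=r2_full - r2_null,
            lrt_stat=5.0, lrt_df=1, lrt_p=lrt_p, n=1000,
        )

    def test_relative_improvement_percentage(self):
        # 0.78% -> 0.93% variance explained is a ~19% relative gain
        report = improvement_report([self._comp("ghq", 0.0078, 0.0093)])
        assert report["improvement_pct"].iloc[0] == pytest.approx(19.23, abs=0.1)

    def test_zero_increment_zero_improvement(self):
        report = improvement_report([self._comp("ghq", 0.005, 0.005)])
        assert report["improvement_pct"].iloc[0] == 0.0

    def test_fdr_applied_across_family(self):
        report = improvement_report(
            [self._comp(t, 0.004, 0.006, lrt_p=p) for t, p in
             zip("abcd", (0.01, 0.02, 0.03, 0.04))]
        )
        np.testing.assert_allclose(report["fdr_lrt_p"], [0.04] * 4)


class TestJointVsCombined:
    def test_combined_model_beats_joint_score(self):
        cfg = SimConfig(
            n_samples=4000, n_snps=600, n_causal_additive=40, n_causal_gxe=40,
            var_additive=0.12, var_gxe=0.06, seed=300,
        )
        panel = simulate_genotypes(cfg)
        expo = simulate_exposure(panel, cfg)
        cov = simulate_covariates(cfg)
        truth = simulate_phenotype(panel, expo.counts, cov, cfg)
        disc, targ = split_panel(panel, 2000)
        gweis = run_gweis(disc, truth.y[:2000], expo.counts[:2000], cov.iloc[:2000])
        comp = joint_vs_combined(
            gweis, disc, targ, truth.y[2000:], cov.iloc[2000:].reset_index(drop=True)
        )
        assert comp.r2_full >= comp.r2_null
        assert comp.lrt_df == 1
        assert comp.lrt_p < 0.05
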