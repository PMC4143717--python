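"""Variable-selection MCMC: catalog bookkeeping and conjugate oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

import longmm as lm
from longmm.bayes import (
    BayesConfig,
    McmcChain,
    build_term_catalog,
    mcmc_run,
    preselect_snps,
    summarize_posterior,
)
from longmm.covariance import BlockKinship, build_spatial_power_block
from longmm.data import expand_to_visits, stacked_trait

from conftest import make_panels


def _cohort(n=25, p=2, seed=0, rho=0.6, counts=(2, 3)):
    panels = make_panels(n, seed=seed, counts=counts)
    gm = lm.simulate_genotypes(n, 150, spacing_bp=1_000_000, seed=seed)
    gm = gm.subset(np.arange(p))
    blocks = [build_spatial_power_block(rho, pp.ages) for pp in panels]
    kin = BlockKinship([pp.individual_id for pp in panels], blocks)
    return panels, gm, kin


class TestTermCatalog:
    @pytest.mark.parametrize("p,q", [(1, 2), (2, 5), (3, 9), (10, 65)])
    def test_term_count_formula(self, p, q):
        panels, gm, _ = _cohort(20, p=p, seed=1)
        cat = build_term_catalog(gm, panels)
        assert cat.q == q == p * (p + 3) // 2

    def test_epistasis_index_round_trip(self):
        panels, gm, _ = _cohort(20, p=8, seed=2)
        cat = build_term_catalog(gm, panels)
        for j in range(8):
            for k in range(j + 1, 8):
                idx = cat.epistasis_index(j, k)
                assert cat.term_kind(idx) == "epistasis"
                assert cat.term_snps(idx) == (j, k)

    def test_columns_are_centered_products(self):
        panels, gm, _ = _cohort(30, p=3, seed=3)
        cat = build_term_catalog(gm, panels)
        centered = gm.dosage - gm.dosage.mean(axis=0)
        main0 = expand_to_visits(panels, centered[:, 0])
        np.testing.assert_allclose(cat.column(0), main0)
        epi = cat.column(cat.epistasis_index(0, 1))
        np.testing.assert_allclose(
            epi, expand_to_visits(panels, centered[:, 0] * centered[:, 1])
        )
        ga = cat.column(cat.gene_age_index(0))
        np.testing.assert_allclose(ga, main0 * cat.ages)

    def test_terms_for_snp_covers_all_kinds(self):
        panels, gm, _ = _cohort(20, p=5, seed=4)
        cat = build_term_catalog(gm, panels)
        terms = cat.terms_for_snp(2)
        kinds = [cat.term_kind(k) for k in terms]
        assert kinds.count("main") == 1
        assert kinds.count("gene_age") == 1
        assert kinds.count("epistasis") == 4

    def test_cap_enforced(self):
        panels, gm, _ = _cohort(20, p=5, seed=5)
        with pytest.raises(ValueError, match="cap"):
            build_term_catalog(gm, panels, max_p=3)


class TestPreselect:
    def _scan(self, p_values):
        return pd.DataFrame(
            {"chrom": "1", "pos": np.arange(len(p_values)) + 1,
             "id": [f"s{j}" for j in range(len(p_values))],
             "p": p_values}
        )

    def test_correlated_pair_keeps_better_ranked(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, 60).astype(float)
        gm = lm.GenotypeMatrix(
            np.column_stack([col, col]),
            pd.DataFrame({"chrom": ["1", "1"], "pos": [1, 2],
                          "id": ["a", "b"]}),
            [f"i{k}" for k in range(60)],
        )
        keep = preselect_snps(self._scan([0.5, 1e-6]), gm, k=2)
        assert list(keep) == [1]  # the smaller p-value wins

    def test_orthogonal_snps_top_k_by_p(self):
        rng = np.random.default_rng(1)
        gm = lm.simulate_genotypes(400, 20, spacing_bp=10_000_000, seed=1)
        pvals = rng.random(20)
        keep = preselect_snps(self._scan(pvals), gm, k=5)
        assert set(keep) == set(np.argsort(pvals)[:5])


class TestChainBookkeeping:
    def test_retained_sample_count_schedule(self):
        """The reference schedule retains exactly 10,000 states."""
        cfg = BayesConfig(iterations=400_000, burn_in=1000, thin=40)
        assert cfg.n_retained == 10_000

    def test_small_run_retains_iterations_over_thin(self):
        panels, gm, kin = _cohort(10, p=1, seed=6)
        cfg = BayesConfig(iterations=220, burn_in=30, thin=10, seed=0)
        chain = mcmc_run(panels, build_term_catalog(gm, panels), kin, cfg)
        assert chain.n_retained == 22

    def test_identical_seed_identical_chain(self):
        panels, gm, kin = _cohort(12, p=2, seed=7)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig(iterations=300, burn_in=50, thin=3, seed=42)
        c1 = mcmc_run(panels, cat, kin, cfg)
        c2 = mcmc_run(panels, cat, kin, cfg)
        np.testing.assert_array_equal(c1.sigma_g, c2.sigma_g)
        np.testing.assert_array_equal(c1.sigma_e2, c2.sigma_e2)
        for a, b in zip(c1.active, c2.active):
            np.testing.assert_array_equal(a, b)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            BayesConfig(iterations=0)
        with pytest.raises(ValueError):
            BayesConfig(thin=0)


class TestConjugateOracles:
    def test_fixed_gamma_beta_posterior_matches_gls(self):
        """Sampler beta moments equal the closed-form GLS posterior.

        gamma is frozen on the two main effects and the variance
        components are held at known values, so the marginal posterior
        of beta is exactly Gaussian with ridge precision 1/tau2.
        """
        panels, gm, kin = _cohort(25, p=2, seed=8)
        cat = build_term_catalog(gm, panels)
        sg, se2 = 0.8, 1.1
        cfg = BayesConfig(iterations=20_000, burn_in=500, thin=5, seed=3)
        fixed = np.zeros(cat.q, dtype=bool)
        fixed[:2] = True
        cov = np.empty((kin.total_dim, 0))
        chain = mcmc_run(panels, cat, kin, cfg, covariates=cov,
                         fixed_gamma=fixed, fix_sigma_g=sg,
                         fix_sigma_e2=se2)
        samples = chain.beta_matrix([0, 1])

        y = stacked_trait(panels)
        var_y = np.var(y)
        tau2 = cfg.h * var_y / 5.0  # h * Var(y) / total expected active
        W = np.column_stack([np.ones(len(y)), cat.column(0), cat.column(1)])
        Sigma = sg ** 2 * sla.block_diag(*kin.blocks) + se2 * np.eye(len(y))
        Si = np.linalg.inv(Sigma)
        D = np.diag([0.0, 1.0 / tau2, 1.0 / tau2])
        post_cov = np.linalg.inv(W.T @ Si @ W + D)
        post_mean = post_cov @ (W.T @ Si @ y)

        R_eff = samples.shape[0] / 5.0  # conservative autocorrelation
        for t in range(2):
            se_mc = np.sqrt(post_cov[t + 1, t + 1] / R_eff)
            assert samples[:, t].mean() == pytest.approx(
                post_mean[t + 1], abs=3 * se_mc
            )
        emp = np.cov(samples.T)
        for a in range(2):
            for b in range(2):
                c_ab = post_cov[a + 1, b + 1]
                se_c = np.sqrt(
                    (post_cov[a + 1, a + 1] * post_cov[b + 1, b + 1]
                     + c_ab ** 2) / R_eff
                )
                assert emp[a, b] == pytest.approx(c_ab, abs=3 * se_c)

    def test_covariate_only_model_matches_closed_form(self):
        """q=0, sigma_g=0: mu and se2 posteriors are standard conjugate."""
        panels, _, kin = _cohort(40, p=1, seed=9)
        cfg = BayesConfig(iterations=20_000, burn_in=500, thin=5, seed=4)
        cov = np.empty((kin.total_dim, 0))
        chain = mcmc_run(panels, None, kin, cfg, covariates=cov,
                         fix_sigma_g=0.0)
        y = stacked_trait(panels)
        N = len(y)
        var_y = np.var(y)
        nu0, s02 = cfg.sigma_e_df, 0.5 * var_y
        # marginal posterior: se2 ~ scaled-inv-chi2(nu0+N-1, ...)
        df_post = nu0 + N - 1
        scale_post = (nu0 * s02 + N * var_y) / df_post
        mean_se2 = df_post * scale_post / (df_post - 2)
        R_eff = chain.n_retained / 5.0
        assert chain.mu.mean() == pytest.approx(
            y.mean(), abs=3 * np.sqrt(mean_se2 / N / R_eff)
        )
        sd_se2 = mean_se2 * np.sqrt(2.0 / (df_post - 4))
        assert chain.sigma_e2.mean() == pytest.approx(
            mean_se2, abs=3 * sd_se2 / np.sqrt(R_eff) + 0.02 * mean_se2
        )

    def test_pure_noise_pips_recover_prior(self):
        """With a vanishing slab, inclusion odds collapse to the prior."""
        panels, gm, kin = _cohort(30, p=4, seed=10)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig(iterations=30_000, burn_in=500, thin=5, seed=5,
                          h=1e-8, expected_main=1.0)
        chain = mcmc_run(panels, cat, kin, cfg)
        pi = cfg.prior_inclusion(cat)  # [main, epi, gene_age]
        counts = np.zeros(cat.q)
        for act in chain.active:
            counts[act] += 1
        pips = counts / chain.n_retained
        R_eff = chain.n_retained / 3.0
        for kind_idx, term_ids in (
            (0, range(cat.p)),
            (2, [cat.gene_age_index(j) for j in range(cat.p)]),
        ):
            mean_pip = np.mean(pips[list(term_ids)])
            se = np.sqrt(pi[kind_idx] * (1 - pi[kind_idx])
                         / (R_eff * cat.p))
            assert mean_pip == pytest.approx(pi[kind_idx], abs=4 * se)


class TestSummaries:
    def _manual_chain(self, cat, active_lists, cfg):
        R = len(active_lists)
        return McmcChain(
            mu=np.zeros(R), beta_e=np.zeros((R, 0)),
            sigma_g=np.ones(R), sigma_e2=np.ones(R),
            active=[np.array(a, dtype=int) for a in active_lists],
            beta_active=[np.ones(len(a)) for a in active_lists],
            q=cat.q, config=cfg, sg_acceptance=0.3,
        )

    def test_pip_equal_prior_gives_unit_bf(self):
        panels, gm, _ = _cohort(20, p=4, seed=11)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig(expected_main=1.0)
        pi_main = cfg.prior_inclusion(cat)[0]  # = 0.25 at p=4
        # activate term 0 in exactly the prior fraction of samples,
        # accounting for the +0.5/+0.5 smoothing: pip=(n1+0.5)/(R+1)
        R, n1 = 197, 49
        assert (n1 + 0.5) / (R + 1) == pi_main
        chain = self._manual_chain(
            cat, [[0]] * n1 + [[]] * (R - n1), cfg
        )
        s = summarize_posterior(chain, cat, cfg)
        row = s.terms[s.terms["term_id"] == 0].iloc[0]
        assert row["bf"] == pytest.approx(1.0)
        assert row["two_ln_bf"] == pytest.approx(0.0)

    def test_always_active_term_has_finite_bf(self):
        panels, gm, _ = _cohort(20, p=2, seed=12)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig()
        chain = self._manual_chain(cat, [[0]] * 150, cfg)
        s = summarize_posterior(chain, cat, cfg)
        assert np.isfinite(s.terms["bf"]).all()

    def test_combined_snp_pip_union_bounds(self):
        panels, gm, kin = _cohort(25, p=3, seed=13)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig(iterations=2000, burn_in=100, thin=2, seed=6)
        chain = mcmc_run(panels, cat, kin, cfg)
        s = summarize_posterior(chain, cat, cfg)
        terms = s.terms
        for j in range(3):
            snp_pip = s.snps["pip"].iloc[j]
            ids = cat.terms_for_snp(j)
            t_pips = terms[terms["term_id"].isin(ids)]["pip"]
            # union probability: at least each member, at most the sum
            assert snp_pip >= t_pips.max() - 1.0 / chain.n_retained
            assert snp_pip <= t_pips.sum() + 1.0 / chain.n_retained

    def test_strong_main_effect_tops_combined_bf(self):
        """A SNP with a large simulated effect outranks every null SNP."""
        hits = 0
        for r in range(3):
            panels = make_panels(100, seed=40 + r, counts=(2, 3))
            gm = lm.simulate_genotypes(100, 12, spacing_bp=10_000_000,
                                       seed=40 + r)
            dosage = gm.dosage[:, 4]
            panels = [
                p.with_trait(p.trait + 1.5 * dosage[i])
                for i, p in enumerate(panels)
            ]
            blocks = [build_spatial_power_block(0.5, p.ages)
                      for p in panels]
            kin = BlockKinship([p.individual_id for p in panels], blocks)
            cat = build_term_catalog(gm, panels)
            cfg = BayesConfig(iterations=4000, burn_in=300, thin=4,
                              seed=50 + r)
            chain = mcmc_run(panels, cat, kin, cfg)
            s = summarize_posterior(chain, cat, cfg)
            hits += s.snps["bf"].idxmax() == 4
        assert hits >= 2

    def test_gated_sweep_still_finds_strong_signal(self):
        panels = make_panels(80, seed=60, counts=(2, 3))
        gm = lm.simulate_genotypes(80, 10, spacing_bp=10_000_000, seed=60)
        dosage = gm.dosage[:, 2]
        panels = [p.with_trait(p.trait + 2.0 * dosage[i])
                  for i, p in enumerate(panels)]
        blocks = [build_spatial_power_block(0.5, p.ages) for p in panels]
        kin = BlockKinship([p.individual_id for p in panels], blocks)
        cat = build_term_catalog(gm, panels)
        cfg = BayesConfig(iterations=3000, burn_in=300, thin=3, seed=61,
                          exhaustive=False)
        chain = mcmc_run(panels, cat, kin, cfg)
        s = summarize_posterior(chain, cat, cfg)
        assert s.snps["bf"].idxmax() == 2
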