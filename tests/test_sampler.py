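"""MCMC sampler correctness: conjugate oracles, prior reproduction,
pair-vs-single equivalence, invariants and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from bvsgwas.data import GeneticMap, GenotypeMatrix
from bvsgwas.model import (BayesianVariableSelection, MCMCConfig, Priors,
                           sample_pi)
from bvsgwas.pedigree import Pedigree
from conftest import make_genotypes, no_phenotype_series


def empty_genotypes(ids):
    gmap = GeneticMap(np.array([], dtype=int), np.array([]))
    return GenotypeMatrix(np.zeros((len(ids), 0), dtype=np.int8), gmap,
                          ids=list(ids))


class TestMeanUpdate:
    def test_conjugate_posterior_oracle(self):
        """y=(2,2,2,2), sigma_e^2=1, no other effects: mu | y ~ N(2, 1/4)."""
        ids = ["a", "b", "c", "d"]
        g = empty_genotypes(ids)
        y = pd.Series([2.0, 2.0, 2.0, 2.0], index=ids)
        model = BayesianVariableSelection(
            y, g, priors=Priors(sigma2_e_init=1.0, var_bounds=(0.5, 2.0)))
        res = model.fit(n_cycles=11_000, burn_in=1_000, thin=1, seed=2,
                        update_variances=False, mh_scale_move=False)
        mu = res.scalars["mu"].to_numpy()
        # draws are iid from N(2, 1/4): 3 MC s.e. on the mean
        assert mu.mean() == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(mu.size))
        assert mu.std() == pytest.approx(0.5, rel=0.1)

    def test_flat_data_centered_at_zero(self):
        ids = list("abcd")
        g = empty_genotypes(ids)
        y = pd.Series(np.zeros(4), index=ids)
        model = BayesianVariableSelection(
            y, g, priors=Priors(sigma2_e_init=1.0, var_bounds=(0.5, 2.0)))
        res = model.fit(n_cycles=6_000, burn_in=1_000, thin=1, seed=3,
                        update_variances=False, mh_scale_move=False)
        mu = res.scalars["mu"].to_numpy()
        assert abs(mu.mean()) < 3 * 0.5 / np.sqrt(mu.size)


class TestPolygenicUpdate:
    def test_blup_shrinkage_two_founders(self):
        """Posterior mean of a_i is the mixed-model shrinkage of y_i."""
        ids = ["f1", "f2"]
        g = empty_genotypes(ids)
        ped = Pedigree(np.array([-1, -1]), np.array([-1, -1]), ids)
        y = pd.Series([1.0, -2.0], index=ids)
        sa2, se2 = 2.0, 1.0
        model = BayesianVariableSelection(
            y, g, ped, priors=Priors(sigma2_a_init=sa2, sigma2_e_init=se2,
                                     var_bounds=(0.5, 4.0)))
        res = model.fit(n_cycles=21_000, burn_in=1_000, thin=1, seed=4,
                        update_mu=False, mu_init=0.0,
                        update_variances=False, mh_scale_move=False)
        shrink = sa2 / (sa2 + se2)
        # MC s.e. of the mean of correlated draws; generous 3x bound
        assert res.polygenic_mean[0] == pytest.approx(shrink * 1.0, abs=0.05)
        assert res.polygenic_mean[1] == pytest.approx(shrink * -2.0, abs=0.05)

    def test_unphenotyped_child_is_parent_average(self):
        ids = ["s", "d", "kid"]
        g = empty_genotypes(ids)
        ped = Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, 1]), ids)
        y = pd.Series([2.0, -1.0, np.nan], index=ids)
        model = BayesianVariableSelection(
            y, g, ped, priors=Priors(sigma2_a_init=1.0, sigma2_e_init=1.0,
                                     var_bounds=(0.5, 4.0)))
        res = model.fit(n_cycles=21_000, burn_in=1_000, thin=1, seed=5,
                        update_mu=False, mu_init=0.0,
                        update_variances=False, mh_scale_move=False)
        parent_avg = (res.polygenic_mean[0] + res.polygenic_mean[1]) / 2
        assert res.polygenic_mean[2] == pytest.approx(parent_avg, abs=0.05)

    def test_tiny_polygenic_variance_shrinks_to_zero(self):
        ids = ["f1", "f2"]
        g = empty_genotypes(ids)
        ped = Pedigree(np.array([-1, -1]), np.array([-1, -1]), ids)
        y = pd.Series([3.0, 3.0], index=ids)
        model = BayesianVariableSelection(
            y, g, ped, priors=Priors(sigma2_a_init=1e-6, sigma2_e_init=1.0,
                                     var_bounds=(1e-8, 4.0)))
        res = model.fit(n_cycles=4_000, burn_in=1_000, thin=1, seed=6,
                        update_mu=False, mu_init=0.0,
                        update_variances=False, mh_scale_move=False)
        assert np.all(np.abs(res.polygenic_mean) < 0.01)


class TestSnpUpdates:
    def _one_snp_model(self, rng, n=200, effect=1.0, sigma_e=1.0):
        codes = rng.binomial(2, 0.5, size=(n, 1)).astype(np.int8)
        g = make_genotypes(codes)
        x = codes[:, 0] - codes[:, 0].mean()
        y = pd.Series(effect * x + rng.normal(0, sigma_e, n),
                      index=g.ids)
        return g, y, x

    def test_conjugate_alpha_posterior_fixed_inclusion(self, rng):
        """With delta pinned to 1 and fixed variances, alpha | y is the
        closed-form normal posterior."""
        g, y, x = self._one_snp_model(rng)
        v1, se2 = 0.5, 1.0
        model = BayesianVariableSelection(
            y, g, priors=Priors(pi0=0.0, sigma2_g0=v1 / 100.0,
                                sigma2_e_init=se2, var_bounds=(0.001, 5.0)))
        res = model.fit(n_cycles=21_000, burn_in=1_000, thin=1, seed=7,
                        update_mu=False, mu_init=0.0, update_pi=False,
                        update_variances=False, mh_scale_move=False)
        s = np.dot(x, x)
        prec = 1.0 / v1 + s / se2
        post_mean = np.dot(x, y.to_numpy()) / se2 / prec
        assert res.pip[0] == pytest.approx(1.0)
        assert res.snp_effect_mean[0] == pytest.approx(
            post_mean, abs=3.0 / np.sqrt(prec * 20_000) + 0.01)

    def test_zero_column_posterior_equals_prior(self, rng):
        """A constant SNP column carries no likelihood: pip -> pi1."""
        codes = np.column_stack([np.full(300, 1), rng.binomial(2, 0.5, 300)])
        g = make_genotypes(codes.astype(np.int8))
        y = pd.Series(rng.normal(size=300), index=g.ids)
        model = BayesianVariableSelection(
            y, g, priors=Priors(pi0=0.9, sigma2_e_init=1.0, var_bounds=(0.1, 5.0)))
        res = model.fit(n_cycles=21_000, burn_in=1_000, thin=1, seed=8,
                        update_pi=False, update_variances=False,
                        mh_scale_move=False)
        se = np.sqrt(0.1 * 0.9 / 20_000) * 10  # generous: draws autocorrelated
        assert res.pip[0] == pytest.approx(0.10, abs=3 * se)

    def test_strong_qtl_detected(self, rng):
        """One SNP explaining a large share of variance: pip > 0.9."""
        n = 500
        codes = rng.binomial(2, 0.5, size=(n, 20)).astype(np.int8)
        g = make_genotypes(codes)
        x = codes[:, 7] - codes[:, 7].mean()
        y = pd.Series(5.0 * x + rng.normal(0, 1.0, n), index=g.ids)
        model = BayesianVariableSelection(y, g)
        res = model.fit(n_cycles=4_000, burn_in=1_000, thin=5, seed=9)
        assert res.pip[7] > 0.9

    def test_pair_and_single_site_same_posterior(self, rng):
        """Joint pair updates and single-site updates target the same
        invariant distribution: posterior inclusion agrees on a toy."""
        n, m = 150, 10
        codes = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
        g = make_genotypes(codes)
        beta = np.zeros(m)
        beta[2] = 0.6
        y = pd.Series(codes @ beta + rng.normal(0, 1.0, n), index=g.ids)
        pips = {}
        for pair in (True, False):
            model = BayesianVariableSelection(y, g)
            cfg = MCMCConfig(n_cycles=21_000, burn_in=1_000, thin=1, seed=10,
                             pair_updates=pair)
            pips[pair] = model.fit(config=cfg).pip
        assert np.max(np.abs(pips[True] - pips[False])) < 0.08

    def test_mixture_variance_ratio_exact_every_cycle(self, desk_fit):
        s = desk_fit.scalars
        assert np.all(s["sigma2_g1"].to_numpy() ==
                      100.0 * s["sigma2_g0"].to_numpy())


class TestPiUpdate:
    def test_no_snps_samples_prior(self, rng):
        draws = [sample_pi(np.array([]), rng=rng) for _ in range(4_000)]
        assert np.mean(draws) == pytest.approx(1 / 101, abs=3 * 0.01 / 63)

    def test_all_included_conjugate_arithmetic(self, rng):
        draws = [sample_pi(np.ones(100), rng=rng) for _ in range(4_000)]
        assert np.mean(draws) == pytest.approx(101 / 201, abs=0.005)

    def test_none_included_large_m(self, rng):
        draws = [sample_pi(np.zeros(6_738), rng=rng) for _ in range(4_000)]
        assert np.mean(draws) == pytest.approx(1 / 6_839, rel=0.1)

    def test_binary_required(self):
        with pytest.raises(ValueError):
            sample_pi(np.array([0.5]))


class TestVarianceUpdates:
    def test_residual_variance_recovery(self, rng):
        """n=1000 pure-noise observations, true sigma_e^2 = 1."""
        ids = [f"i{k}" for k in range(1_000)]
        g = empty_genotypes(ids)
        y = pd.Series(rng.normal(0, 1.0, 1_000), index=ids)
        model = BayesianVariableSelection(y, g)
        res = model.fit(n_cycles=11_000, burn_in=1_000, thin=1, seed=11,
                        update_mu=False, mu_init=0.0, mh_scale_move=False)
        se2 = res.scalars["sigma2_e"].to_numpy()
        sse = float(np.dot(y, y))
        oracle_mean = sse / (1_000 - 4)  # inverse-gamma((n-2)/2, SSE/2) mean
        assert se2.mean() == pytest.approx(oracle_mean, rel=0.02)

    def test_zero_residuals_pile_at_lower_bound(self):
        ids = list("abcdef")
        g = empty_genotypes(ids)
        y = pd.Series(np.zeros(6), index=ids)
        model = BayesianVariableSelection(
            y, g, priors=Priors(var_bounds=(0.25, 2.0)))
        res = model.fit(n_cycles=2_000, burn_in=500, thin=1, seed=12,
                        update_mu=False, mu_init=0.0, mh_scale_move=False)
        assert np.all(res.scalars["sigma2_e"].to_numpy() == 0.25)


class TestPriorReproduction:
    """No-data (Geweke-style) runs must reproduce every prior marginal;
    this specifically validates the Jacobian of the ratio-constrained
    Metropolis-Hastings scaling move."""

    @pytest.fixture(scope="class")
    @staticmethod
    def prior_run():
        rng = np.random.default_rng(0)
        gmap = GeneticMap.equally_spaced(1, 6)
        geno = GenotypeMatrix(rng.integers(0, 3, (5, 6)).astype(np.int8), gmap)
        ped = Pedigree(np.array([-1, -1, -1, 0, 0]),
                       np.array([-1, -1, -1, 1, 2]), list(geno.ids))
        y = no_phenotype_series(geno.ids)
        model = BayesianVariableSelection(
            y, geno, ped, priors=Priors(var_bounds=(0.5, 2.0)))
        return model.fit(n_cycles=62_000, burn_in=2_000, thin=1, seed=3)

    @pytest.mark.parametrize("param", ["sigma2_g0", "sigma2_a", "sigma2_e"])
    def test_uniform_variance_prior_moments(self, prior_run, param):
        x = prior_run.scalars[param].to_numpy()
        # Uniform(0.5, 2): mean 1.25, sd 0.433; autocorrelated draws -> use
        # 3 x (sd / sqrt(ESS)) as the tolerance
        from bvsgwas.diagnostics import effective_sample_size
        ess = max(effective_sample_size(x), 50.0)
        assert x.mean() == pytest.approx(1.25, abs=3 * 0.433 / np.sqrt(ess))
        assert x.std() == pytest.approx(np.sqrt((2 - 0.5) ** 2 / 12), rel=0.10)
        assert x.min() >= 0.5 and x.max() <= 2.0

    def test_pi1_beta_prior_moments(self, prior_run):
        x = prior_run.scalars["pi1"].to_numpy()
        prior_sd = np.sqrt(100 / (101**2 * 102))
        assert x.mean() == pytest.approx(1 / 101, abs=3 * prior_sd / np.sqrt(500))


class TestChainMechanics:
    def test_bit_identical_given_seed(self, rng):
        codes = rng.binomial(2, 0.4, size=(60, 15)).astype(np.int8)
        g = make_genotypes(codes)
        y = pd.Series(rng.normal(size=60), index=g.ids)
        a = BayesianVariableSelection(y, g).fit(n_cycles=2_000, burn_in=500,
                                                thin=5, seed=42)
        b = BayesianVariableSelection(y, g).fit(n_cycles=2_000, burn_in=500,
                                                thin=5, seed=42)
        assert a.scalars.equals(b.scalars)
        assert np.array_equal(a.pip, b.pip)
        assert np.array_equal(a.snp_effect_mean, b.snp_effect_mean)

    def test_residual_drift_bounded(self, desk_fit):
        assert desk_fit.residual_drift < 1e-8

    def test_stored_cycle_count(self, desk_fit):
        assert len(desk_fit.scalars) == (10_000 - 2_000) // 10
        cfg = MCMCConfig(n_cycles=52_000, burn_in=2_000, thin=10)
        assert cfg.n_stored == 5_000

    def test_mh_acceptance_tuned_near_half(self, desk_fit):
        assert 0.3 <= desk_fit.mh_accept_rate <= 0.7

    def test_burnin_must_precede_cycles(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_cycles=1_000, burn_in=1_000)

    def test_null_polygenic_simulation_pip_at_prior(self):
        """No-QTL data: mean inclusion probability stays at the prior mean."""
        from dataclasses import replace

        from bvsgwas.simulate import PopSimConfig, simulate_population

        cfg = replace(PopSimConfig().desk(), qtl_spec=(), polygenic_share=1.0,
                      snps_per_chrom=100, n_dams_per_sire=3,
                      n_offspring_per_dam=5, phenotyped_per_family=3)
        sim = simulate_population(cfg, seed=3)
        model = BayesianVariableSelection.from_simulation(sim)
        res = model.fit(n_cycles=6_000, burn_in=1_000, thin=10, seed=3)
        assert res.pip.mean() == pytest.approx(1 / 101, abs=0.01)

    def test_heritability_recovery_single_seed(self, desk_sim, desk_fit):
        h2 = desk_fit.heritability()["mean"]
        assert abs(h2 - 0.30) < 0.08

    def test_h2_reduces_to_polygenic_share_without_snps(self, desk_fit):
        sa = desk_fit.scalars["sigma2_a"].to_numpy()
        se = desk_fit.scalars["sigma2_e"].to_numpy()
        assert np.allclose(desk_fit.h2_samples(include_snp=False),
                           sa / (sa + se))

    def test_h2_in_unit_interval(self, desk_fit):
        h2 = desk_fit.h2_samples()
        assert np.all((h2 > 0) & (h2 < 1))
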