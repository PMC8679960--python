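"""Window plans, genotype likelihoods and Bayesian posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

import lapaint as lp
from lapaint.panel import MISSING, GenotypeVector, Site


def make_sites(n, chrom="1"):
    return [Site(chrom, 1000 * (i + 1), "A", "G") for i in range(n)]


class TestWindowPlan:
    def test_covers_all_sites_contiguously(self):
        sites = make_sites(7, "1") + make_sites(5, "2")
        plan = lp.plan_windows(sites, L=3)
        assert plan.boundaries == [(0, 3), (3, 6), (6, 7), (7, 10), (10, 12)]
        assert plan.chroms == ["1", "1", "1", "2", "2"]

    def test_window_count_is_ceiling_per_chromosome(self):
        sites = make_sites(100, "1") + make_sites(101, "2")
        plan = lp.plan_windows(sites, L=50)
        assert plan.n_windows == 2 + 3


class TestGenotypeLoglik:
    def test_diploid_het_symmetric(self):
        assert lp.genotype_loglik(1, 0.5, "diploid") == pytest.approx(np.log(0.5))

    def test_haploid_is_bernoulli(self):
        assert lp.genotype_loglik(1, 0.9, "haploid") == pytest.approx(np.log(0.9))
        assert lp.genotype_loglik(0, 0.9, "haploid") == pytest.approx(np.log(0.1))

    @pytest.mark.parametrize("f", [0.01, 0.3, 0.5, 0.77, 0.99])
    def test_diploid_normalizes_over_genotypes(self, f):
        total = sum(np.exp(lp.genotype_loglik(g, f, "diploid")) for g in (0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_contributes_zero(self):
        assert lp.genotype_loglik(MISSING, 0.3, "diploid") == 0.0

    def test_rejects_boundary_frequencies(self):
        with pytest.raises(ValueError):
            lp.genotype_loglik(1, 1.0, "diploid")


class TestWindowLoglik:
    def test_single_site_window_equals_genotype_loglik(self):
        f = np.array([[0.3, 0.8]])
        out = lp.window_loglik(np.array([2]), f, "diploid")
        np.testing.assert_allclose(
            out, [lp.genotype_loglik(2, 0.3, "diploid"),
                  lp.genotype_loglik(2, 0.8, "diploid")])

    def test_identical_frequencies_give_equal_components(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=20)
        f = np.tile(rng.uniform(0.1, 0.9, size=(20, 1)), (1, 4))
        out = lp.window_loglik(g, f, "diploid")
        assert np.ptp(out) == pytest.approx(0.0, abs=1e-12)

    def test_matches_linear_space_product(self):
        """10-SNP window equals the log of the brute-force probability product."""
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=10)
        f = rng.uniform(0.05, 0.95, size=(10, 3))
        out = lp.window_loglik(g, f, "diploid")
        from math import comb
        for k in range(3):
            prod = 1.0
            for i in range(10):
                fi = f[i, k]
                prod *= comb(2, int(g[i])) * fi ** g[i] * (1 - fi) ** (2 - g[i])
            assert out[k] == pytest.approx(np.log(prod), abs=1e-10)

    def test_all_missing_window_is_flat(self):
        g = np.full(5, MISSING)
        out = lp.window_loglik(g, np.full((5, 3), 0.4), "diploid")
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_invariant_to_snp_order(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 2, size=30)
        f = rng.uniform(0.1, 0.9, size=(30, 3))
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            lp.window_loglik(g, f, "haploid"),
            lp.window_loglik(g[perm], f[perm], "haploid"), atol=1e-12)


class TestPosterior:
    def test_uniform_prior_equal_likelihoods(self):
        out = lp.posterior(np.zeros(4), np.full(4, 0.25))
        np.testing.assert_allclose(np.exp(out), np.full(4, 0.25), atol=1e-12)

    def test_direct_bayes_arithmetic(self):
        out = lp.posterior(np.log([0.2, 0.1]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(np.exp(out), [2 / 3, 1 / 3], atol=1e-12)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=50)
    def test_matches_naive_normalization(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        lik = rng.uniform(0.01, 1.0, size=K)
        prior = rng.dirichlet(np.ones(K))
        prior = prior / prior.sum()
        out = lp.posterior(np.log(lik), prior)
        naive = prior * lik / (prior * lik).sum()
        np.testing.assert_allclose(np.exp(out), naive, atol=1e-12)

    def test_zero_prior_floored_and_renormalized(self):
        out = lp.posterior(np.zeros(3), np.array([0.5, 0.5, 0.0]))
        assert np.isfinite(out).all()
        assert np.exp(out)[2] < 1e-8

    def test_hard_prior_forbids_state(self):
        out = lp.posterior(np.zeros(3), np.array([0.5, 0.5, 0.0]),
                           hard_prior=True)
        assert out[2] == -np.inf

    def test_degenerate_posterior_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            lp.posterior(np.array([-np.inf, 0.0]), np.array([1.0, 0.0]),
                         hard_prior=True)

    def test_no_underflow_for_huge_windows(self):
        """Rows still normalize with 10,000-SNP-scale log-likelihoods."""
        rng = np.random.default_rng(7)
        loglik = rng.uniform(-1.5, -0.5, size=(20, 3)) * 10_000
        out = lp.posterior(loglik, np.full(3, 1 / 3))
        np.testing.assert_allclose(np.exp(out).sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(logsumexp(out, axis=1)).all()


class TestComputeEmissions:
    def test_rows_normalize_and_argmax_matches_likelihood(self, small_sim):
        panel = small_sim["panel"]
        hapA, _ = lp.split_phased_haplotypes(small_sim["sample"])
        plan = lp.plan_windows(panel.sites, 50)
        em = lp.compute_emissions(hapA, panel, plan)
        np.testing.assert_allclose(np.exp(em.logpost).sum(axis=1), 1.0,
                                   atol=1e-9)
        # uniform prior: posterior argmax equals likelihood argmax per window
        np.testing.assert_array_equal(em.logpost.argmax(axis=1),
                                      em.loglik.argmax(axis=1))

    def test_likelihood_emission_ignores_informative_prior(self, small_sim):
        panel = small_sim["panel"]
        hapA, _ = lp.split_phased_haplotypes(small_sim["sample"])
        plan = lp.plan_windows(panel.sites, 50)
        skew = np.array([0.9, 0.05, 0.05])
        em_post = lp.compute_emissions(hapA, panel, plan, prior=skew)
        em_lik = lp.compute_emissions(hapA, panel, plan, prior=skew,
                                      likelihood_emission=True)
        uniform = lp.compute_emissions(hapA, panel, plan)
        np.testing.assert_allclose(em_lik.logpost, uniform.logpost, atol=1e-12)
        assert not np.allclose(em_post.logpost, em_lik.logpost)
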