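"""HKY fitting, branch-length MCMC, empirical-Bayes shrinkage and omega."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import simpson

from bcrstar.codons import codon_index
from bcrstar.hky import HKYTriple, fit_hky_triple, mcmc_branch_length
from bcrstar.pairs import CodonPair
from bcrstar.selection import (GammaPoissonFit, SiteCountTable, aggregate,
                               fit_gamma_poisson,
                               gamma_poisson_marginal_loglik, omega_per_site,
                               posterior_rate_draws)
from bcrstar.simulate import GY94Params, simulate_star


@pytest.fixture(scope="module")
def hky():
    return HKYTriple(kappa=[2.0, 2.0, 2.0], pi=np.full((3, 4), 0.25),
                     rel_rate=np.ones(3))


class TestHKYTriple:
    def test_kappa_one_equals_jc_likelihood(self):
        """With kappa=1 and equal frequencies the HKY pair likelihood
        reduces to Jukes-Cantor."""
        model = HKYTriple(kappa=np.ones(3), pi=np.full((3, 4), 0.25),
                          rel_rate=np.ones(3))
        counts = np.zeros((3, 4, 4))
        counts[0, 0, 0] = 10
        counts[1, 1, 2] = 1
        counts[2, 3, 3] = 5
        t = 0.07
        ll = model.pair_loglik(counts, t)
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = 10 * np.log(p_same) + np.log(p_diff) + 5 * np.log(p_same)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_recovery_from_simulation(self):
        """kappa and relative rates recovered from codon data simulated
        with kappa=2 and equal frequencies."""
        rng = np.random.default_rng(8)
        from bcrstar.codons import SENSE_CODONS

        root = SENSE_CODONS[rng.choice(61, size=120)]
        aln = simulate_star(root, 600, 0.1, GY94Params(kappa=2.0, omega=1.0),
                            seed=9)
        pairs = [CodonPair(str(i), root, aln[i]) for i in range(600)]
        fit = fit_hky_triple(pairs)
        assert fit.converged
        for p in range(3):
            assert fit.kappa[p] == pytest.approx(2.0, rel=0.25)
        assert np.allclose(fit.rel_rate, 1.0, atol=0.2)

    def test_degenerate_data_flagged(self):
        germ = np.array([codon_index("CTT")] * 10)
        pairs = [CodonPair(str(i), germ, germ.copy()) for i in range(5)]
        fit = fit_hky_triple(pairs)
        assert not fit.converged


class TestBranchMCMC:
    def test_prior_recovery_with_empty_data(self, hky):
        """No data: the sampler must return draws from Exp(mean 0.1)."""
        empty = np.zeros((3, 4, 4))
        draws = np.concatenate([
            mcmc_branch_length(empty, hky, prior_mean=0.1,
                               iters=4000, thin=8, seed=s)
            for s in range(20)])
        assert draws.size == 10000
        assert draws.mean() == pytest.approx(0.1, abs=0.01)

    def test_retained_sample_count(self, hky):
        counts = np.zeros((3, 4, 4))
        counts[:, 0, 0] = 30
        counts[0, 0, 2] = 1
        samples = mcmc_branch_length(counts, hky, iters=20000, thin=40, seed=1)
        assert samples.shape == (500,)

    def test_posterior_mean_matches_quadrature(self, hky):
        """30-codon pair: MCMC posterior mean agrees with numerical
        quadrature of prior x likelihood over a dense grid."""
        rng = np.random.default_rng(5)
        from bcrstar.codons import SENSE_CODONS

        root = SENSE_CODONS[rng.choice(61, size=30)]
        aln = simulate_star(root, 1, 0.08, GY94Params(kappa=2.0), seed=6)
        pair = CodonPair("x", root, aln[0])
        counts = pair.position_count_matrices()
        prior_mean = 0.1

        grid = np.linspace(1e-6, 1.5, 100000)
        logpost = np.array([hky.pair_loglik(counts, t) for t in
                            grid[::100]])  # coarse loglik, interpolated
        ll = np.interp(grid, grid[::100], logpost)
        lp = ll - grid / prior_mean
        w = np.exp(lp - lp.max())
        quad_mean = simpson(grid * w, x=grid) / simpson(w, x=grid)

        chains = [mcmc_branch_length(counts, hky, prior_mean=prior_mean,
                                     iters=4000, thin=8, seed=100 + k)
                  for k in range(20)]
        means = np.array([c.mean() for c in chains])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert means.mean() == pytest.approx(quad_mean, abs=3 * se + 1e-4)


class TestGammaPoisson:
    def test_conjugate_posterior_matches_analytic(self):
        """Posterior draws follow Gamma(alpha+C, beta+t) exactly
        (KS test over random configurations)."""
        rng = np.random.default_rng(0)
        for k in range(20):
            alpha, beta = rng.uniform(0.2, 5.0), rng.uniform(0.2, 30.0)
            C, t = rng.uniform(0, 20), rng.uniform(0, 50)
            fit = GammaPoissonFit(alpha, beta, None, "gamma")
            draws = posterior_rate_draws(C, t, fit, n_draws=100000, seed=k)
            p = stats.kstest(draws, "gamma", args=(alpha + C, 0,
                                                   1.0 / (beta + t))).pvalue
            assert p > 0.01

    def test_posterior_mean_closed_form_vs_monte_carlo(self):
        fit = GammaPoissonFit(2.0, 20.0, None, "gamma")
        draws = posterior_rate_draws(3.0, 40.0, fit, n_draws=10 ** 6, seed=3)
        expected = (2.0 + 3.0) / (20.0 + 40.0)
        assert draws.mean() == pytest.approx(expected, rel=3e-3)

    def test_shrinkage_limits(self):
        fit = GammaPoissonFit(2.0, 20.0, None, "gamma")
        prior_mean = 2.0 / 20.0
        small_t = posterior_rate_draws(5.0, 1e-9, fit, 200000, seed=1).mean()
        assert small_t == pytest.approx((2.0 + 5.0) / 20.0, rel=0.02)
        big_t = posterior_rate_draws(5000.0, 10000.0, fit, 200000, seed=2).mean()
        assert big_t == pytest.approx(0.5, rel=0.02)
        no_data = posterior_rate_draws(0.0, 0.0, fit, 200000, seed=3)
        assert no_data.mean() == pytest.approx(prior_mean, rel=0.02)

    def test_hyperparameter_recovery(self):
        """alpha, beta recovered from simulated counts with heterogeneous
        exposures at L=500 sites."""
        rng = np.random.default_rng(11)
        alpha, beta = 2.0, 20.0
        t = rng.uniform(5.0, 50.0, size=500)
        lam = rng.gamma(alpha, 1.0 / beta, size=500)
        C = rng.poisson(lam * t)
        fit = fit_gamma_poisson(C, t)
        assert fit.fit_mode == "gamma"
        assert fit.alpha == pytest.approx(alpha, rel=0.25)
        assert fit.beta == pytest.approx(beta, rel=0.25)
        # ML optimality: fitted likelihood beats the generating parameters
        ll_hat = gamma_poisson_marginal_loglik(fit.alpha, fit.beta, C, t)
        ll_true = gamma_poisson_marginal_loglik(alpha, beta, C, t)
        assert ll_hat >= ll_true - 1e-6

    def test_equal_counts_trigger_pooled_fallback(self):
        C = np.full(20, 4.0)
        t = np.full(20, 2.0)
        fit = fit_gamma_poisson(C, t)
        assert fit.fit_mode == "pooled_poisson"
        assert fit.lam == pytest.approx(2.0)

    def test_all_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_poisson(np.ones(5), np.zeros(5))


class TestAggregate:
    def test_exposures_and_coverage(self):
        cov1 = np.array([True] * 5 + [False] * 5)
        cov2 = np.ones(10, dtype=bool)
        table = aggregate(
            [(np.ones(10), np.zeros(10)), (np.ones(10), np.ones(10))],
            [0.05, 0.02], [cov1, cov2], L=10)
        assert np.allclose(table.exposure[:5], 0.07)
        assert np.allclose(table.exposure[5:], 0.02)
        assert (table.coverage == cov1.astype(int) + 1).all()
        assert table.n_counts.sum() == 20

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = [(rng.random(6), rng.random(6)) for _ in range(4)]
        ts = rng.random(4).tolist()
        covs = [rng.random(6) > 0.3 for _ in range(4)]
        a = aggregate(counts, ts, covs, 6)
        order = [2, 0, 3, 1]
        b = aggregate([counts[i] for i in order], [ts[i] for i in order],
                      [covs[i] for i in order], 6)
        assert np.allclose(a.exposure, b.exposure)
        assert np.allclose(a.n_counts, b.n_counts)

    def test_exposure_coverage_consistency_enforced(self):
        with pytest.raises(ValueError):
            SiteCountTable(np.zeros(2), np.zeros(2),
                           np.array([0.1, 0.0]), np.array([0, 1]))


def test_amino_acid_profile_counts_productive_only():
    from bcrstar.selection import amino_acid_profile

    germ = np.array([codon_index("CTT"), codon_index("GGG")])  # Leu, Gly
    p1 = CodonPair("a", germ, np.array([codon_index("CTT"), codon_index("GGA")]))
    p2 = CodonPair("b", germ, np.array([codon_index("ATT"), -1]))
    p3 = CodonPair("c", germ, germ.copy())  # out-of-frame: ignored
    prof = amino_acid_profile([p1, p2, p3],
                              ["productive", "productive", "out_of_frame"])
    site0 = prof[prof.site == 0].set_index("amino_acid")
    assert site0.loc["L", "count"] == 1       # CTT
    assert site0.loc["I", "count"] == 1       # ATT
    assert np.isclose(site0["frequency"].sum(), 1.0)
    site1 = prof[prof.site == 1]
    assert site1["count"].sum() == 1          # p2 uncovered, p3 out-of-frame


def test_plot_omega_renders_classified_sites():
    from bcrstar.selection import OmegaEstimate, SelectionResults

    estimates = [
        OmegaEstimate(0, 0.2, 0.1, 0.5, "negative", 200, 200),
        OmegaEstimate(1, 1.0, 0.6, 1.5, "neutral", 200, 200),
        OmegaEstimate(2, np.nan, np.nan, np.nan, "unclassifiable", 10, 10),
    ]
    res = SelectionResults(model=None, hky=None, tables={}, fits={},
                           estimates=estimates, branch_means=np.zeros(1))
    ax = res.plot_omega()
    # one marker per classified site, skipping the unclassifiable one
    assert len(ax.lines) >= 2
    assert ax.get_yscale() == "log"


class TestOmegaPerSite:
    def _draws(self, rng, mean, n=2000):
        return rng.gamma(100.0, mean / 100.0, size=n)

    def test_identical_posteriors_neutral(self):
        rng = np.random.default_rng(0)
        args = [self._draws(rng, 1.0) for _ in range(4)]
        est = omega_per_site(0, *args, coverage_productive=500,
                             coverage_control=500, min_coverage=100,
                             germline_aa="L")
        assert est.median == pytest.approx(1.0, abs=0.1)
        assert est.lo < 1.0 < est.hi
        assert est.classification == "neutral"

    def test_doubled_numerator_gives_omega_two(self):
        rng = np.random.default_rng(1)
        num_n = self._draws(rng, 2.0)
        others = [self._draws(rng, 1.0) for _ in range(3)]
        est = omega_per_site(0, num_n, *others, coverage_productive=500,
                             coverage_control=500, min_coverage=100,
                             germline_aa="L")
        assert est.median == pytest.approx(2.0, rel=0.1)
        assert est.classification == "positive"

    def test_coverage_below_threshold_unclassifiable(self):
        rng = np.random.default_rng(2)
        args = [self._draws(rng, 1.0) for _ in range(4)]
        est = omega_per_site(0, *args, coverage_productive=99,
                             coverage_control=500, min_coverage=100,
                             germline_aa="L")
        assert est.classification == "unclassifiable"
        assert np.isfinite(est.median)  # the estimate itself is still reported

    @pytest.mark.parametrize("aa", ["W", "M"])
    def test_trp_met_unclassifiable(self, aa):
        rng = np.random.default_rng(3)
        args = [self._draws(rng, 1.0) for _ in range(4)]
        est = omega_per_site(0, *args, coverage_productive=500,
                             coverage_control=500, min_coverage=100,
                             germline_aa=aa)
        assert est.classification == "unclassifiable"

    def test_interval_ordering(self):
        rng = np.random.default_rng(4)
        args = [self._draws(rng, 0.3) for _ in range(4)]
        est = omega_per_site(0, *args, coverage_productive=500,
                             coverage_control=500, min_coverage=100,
                             germline_aa="L")
        assert est.lo <= est.median <= est.hi
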