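"""Hierarchical Bayesian sampler: priors, diagnostics, HPDI, contrasts."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from gammaxo.bayes import (GroupData, HierModelSpec, contrasts, gelman_rubin,
                           group_crossovers, hpdi, log_posterior, run_mcmc)
from gammaxo.likelihood import ChromosomeXO, gamma_loglik

from conftest import make_metadata, simulate_group


def prior_only_data(genotypes=()):
    return GroupData(genotypes=list(genotypes), groups=[], compiled={})


class TestHPDI:
    def test_shortest_window_of_uniform_grid(self):
        lo, hi = hpdi(np.arange(1.0, 101.0), 0.95)
        assert hi - lo == 94.0  # any 95-point window; ties broken leftmost

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_search(self, seed):
        rng = np.random.default_rng(seed)
        draws = rng.gamma(3.0, 2.0, size=500)
        lo, hi = hpdi(draws, 0.9)
        s = np.sort(draws)
        m = math.ceil(0.9 * s.size)
        widths = [(s[i + m - 1] - s[i], s[i], s[i + m - 1])
                  for i in range(s.size - m + 1)]
        bw, blo, bhi = min(widths)
        assert (lo, hi) == (blo, bhi)

    def test_agrees_with_arviz(self):
        import arviz

        rng = np.random.default_rng(3)
        draws = rng.normal(size=4000)
        lo, hi = hpdi(draws, 0.94)
        ref = arviz.hdi(draws, hdi_prob=0.94)
        assert lo == pytest.approx(ref[0], abs=0.02)
        assert hi == pytest.approx(ref[1], abs=0.02)

    def test_skewed_sample_beats_equal_tails(self):
        rng = np.random.default_rng(4)
        draws = rng.lognormal(0.0, 0.8, size=5000)
        _, hi = hpdi(draws, 0.95)
        assert hi < np.percentile(draws, 97.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(1000.0), 1.2)
        with pytest.raises(ValueError):
            hpdi(np.arange(10.0), 0.9)


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.normal(size=(4, 5000))
        assert gelman_rubin(chains) < 1.02

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(6)
        chains = np.stack([rng.normal(0.0, 1.0, 2000),
                           rng.normal(5.0, 1.0, 2000)])
        r = gelman_rubin(chains)
        # closed form: B/n ~ 2*(2.5)^2, W ~ 1 -> R ~ sqrt(1 + 12.5)
        assert r > 3.0

    def test_constant_chains_return_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert gelman_rubin(np.ones((3, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestLogPosterior:
    def test_empty_data_reduces_to_prior(self):
        from scipy.stats import norm

        spec = HierModelSpec()
        data = prior_only_data(["g1"])
        theta = np.array([0.7, -0.2, 0.1])
        expected = (norm.logpdf(0.7, 1.0, math.sqrt(0.5))
                    + norm.logpdf(-0.2, 0.0, math.sqrt(0.5))
                    + norm.logpdf(0.1, 0.0, math.sqrt(0.5)))
        assert log_posterior(theta, data, spec) == pytest.approx(expected)

    def test_intercept_shift_changes_prior_only(self):
        """Moving mass between beta0 and the beta_i leaves every group nu —
        hence the likelihood — unchanged."""
        xos = simulate_group(9.0, n_ind=10, seed=1)
        meta = make_metadata([c.individual for c in xos])
        data = group_crossovers(xos, meta)
        spec = HierModelSpec()
        theta = np.array([1.2, -0.3, 0.0])
        shifted = np.array([1.7, -0.8, 0.0])
        ll = lambda t: (log_posterior(t, data, spec)
                        - log_posterior(t, prior_only_data(data.genotypes),
                                        spec))
        assert ll(theta) == pytest.approx(ll(shifted), rel=1e-9)

    def test_mode_shrinks_toward_prior(self):
        """With one young group, the 1-D posterior mode of beta0 sits
        between log nu_MLE and the prior mean (grid-search oracle)."""
        from gammaxo.fit import fit_gamma

        xos = simulate_group(9.0, n_ind=12, seed=2)
        meta = make_metadata([c.individual for c in xos])
        data = group_crossovers(xos, meta)
        spec = HierModelSpec()
        grid = np.linspace(0.0, 3.5, 400)
        lp = [log_posterior(np.array([b, 0.0, 0.0]), data, spec)
              for b in grid]
        mode = grid[int(np.argmax(lp))]
        mle = math.log(fit_gamma(xos).nu_hat)
        assert min(mle, spec.mu) - 0.05 < mode < max(mle, spec.mu) + 0.05

    def test_nonfinite_theta(self):
        data = prior_only_data(["g"])
        assert log_posterior(np.array([np.nan, 0, 0]), data,
                             HierModelSpec()) == -math.inf


class TestSampler:
    def test_prior_only_run_recovers_prior_moments(self):
        """With no data the Metropolis sampler must reproduce the prior:
        a Gaussian target, so this doubles as a detailed-balance check."""
        spec = HierModelSpec(iterations=6000, burnin=1000, chains=2, seed=3,
                             tau2=0.25)
        post = run_mcmc(spec, prior_only_data(["g1"]))
        flat = post.flat
        assert flat.shape == (2 * 5000, 3)
        assert flat[:, 0].mean() == pytest.approx(1.0, abs=0.1)
        assert flat[:, 0].var() == pytest.approx(0.5, abs=0.1)
        assert flat[:, 1].mean() == pytest.approx(0.0, abs=0.1)
        assert flat[:, 2].var() == pytest.approx(0.5, abs=0.1)
        assert (post.rhat < 1.05).all()

    def test_same_seed_identical_chains(self):
        xos = simulate_group(9.0, n_ind=6, seed=4)
        meta = make_metadata([c.individual for c in xos])
        data = group_crossovers(xos, meta)
        spec = HierModelSpec(iterations=400, burnin=100, chains=2, seed=9)
        a = run_mcmc(spec, data)
        b = run_mcmc(spec, data)
        assert np.array_equal(a.draws, b.draws)

    def test_posterior_concentrates_with_data(self):
        """Posterior SD of log nu shrinks monotonically as data grow."""
        sds = []
        for n_ind in (8, 32, 128):
            xos = simulate_group(9.0, n_ind=n_ind, seed=5)
            meta = make_metadata([c.individual for c in xos])
            data = group_crossovers(xos, meta)
            spec = HierModelSpec(iterations=3000, burnin=1000, chains=2,
                                 seed=6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = run_mcmc(spec, data)
            sds.append(np.log(post.nu_draws("AxB", "young")).std())
        assert sds[0] > sds[1] > sds[2]

    def test_spline_cache_matches_exact_sampler(self):
        xos = simulate_group(9.0, n_ind=6, seed=7)
        meta = make_metadata([c.individual for c in xos])
        data = group_crossovers(xos, meta)
        spec = HierModelSpec(iterations=300, burnin=50, chains=2, seed=10)
        fast = run_mcmc(spec, data, cache_grid=True)
        exact = run_mcmc(spec, data, cache_grid=False)
        # identical proposal streams; acceptance decisions may flip only if
        # the interpolation error crosses a threshold, which it must not
        assert np.allclose(fast.draws, exact.draws)


@pytest.fixture(scope="module")
def posterior():
    xos = (simulate_group(12.0, n_ind=25, seed=8, prefix="a")
           + simulate_group(7.5, n_ind=25, seed=9, prefix="b"))
    meta = pd.concat([
        make_metadata([f"a{i}" for i in range(25)], genotype="AxB"),
        make_metadata([f"b{i}" for i in range(25)], genotype="BxA"),
    ], ignore_index=True)
    data = group_crossovers(xos, meta)
    spec = HierModelSpec(iterations=3000, burnin=1000, chains=2, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_mcmc(spec, data)


class TestContrasts:
    def test_identical_groups_ratio_exactly_one(self, posterior):
        tab = contrasts(posterior, pairs=[("AxB", "AxB")], include_age=False)
        assert tab["ratio_mean"].iloc[0] == 1.0
        assert tab["hpdi95_lo"].iloc[0] == 1.0

    def test_recovers_simulated_ratio(self, posterior):
        """True nu ratio 12/7.5 = 1.6 lies inside the 95% HPDI."""
        tab = contrasts(posterior, pairs=[("AxB", "BxA")], include_age=False)
        row = tab.iloc[0]
        assert row["hpdi95_lo"] < 1.6 < row["hpdi95_hi"]
        assert row["ratio_mean"] == pytest.approx(1.6, rel=0.25)

    def test_unknown_group_rejected(self, posterior):
        with pytest.raises(KeyError):
            contrasts(posterior, pairs=[("AxB", "nonexistent")])
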