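import numpy as np
import pytest

import cocult as cc


def chains_to_samples(chains):
    """Wrap an (m, n) array of scalar draws as single-parameter samples."""
    m, n = chains.shape
    prior = cc.PriorSpec(bounds={"x": (1e-300, 1e300)}, scales={"x": "linear"})
    return cc.PosteriorSamples(
        draws=chains.reshape(-1, 1),
        loglik=np.zeros(m * n),
        chain=np.repeat(np.arange(m), n),
        iteration=np.tile(np.arange(n), m),
        param_names=("x",),
        model="direct",
        prior=prior,
    )


class TestGelmanRubin:
    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((5, 10_000))
        gr = cc.gelman_rubin(chains_to_samples(chains + 100.0))
        assert gr.rhat["x"] < 1.01
        assert gr.converged

    def test_stuck_chains_with_distinct_means_fail(self):
        chains = np.tile(np.arange(5.0)[:, None], (1, 50))
        gr = cc.gelman_rubin(chains_to_samples(chains))
        assert gr.rhat["x"] > 1.2
        assert not gr.converged

    def test_duplicated_chain_is_lower_bound(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal(500)
        gr = cc.gelman_rubin(chains_to_samples(np.tile(one, (5, 1))))
        assert gr.rhat["x"] == pytest.approx(1.0, abs=0.01)

    def test_unequal_chains_truncated_with_warning(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(250)
        chain = np.array([0] * 100 + [1] * 150)
        s = cc.PosteriorSamples(
            draws=draws.reshape(-1, 1),
            loglik=np.zeros(250),
            chain=chain,
            iteration=np.arange(250),
            param_names=("x",),
            model="direct",
            prior=cc.PriorSpec(bounds={"x": (1e-3, 1e3)}, scales={"x": "linear"}),
        )
        with pytest.warns(UserWarning, match="truncating"):
            cc.gelman_rubin(s)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            cc.gelman_rubin(chains_to_samples(np.ones((5, 5))))


class TestPriorSpec:
    def test_sampling_respects_bounds_and_scale(self):
        prior = cc.default_direct_prior()
        rng = np.random.default_rng(0)
        draws = prior.sample(rng, 5000)
        assert np.all(prior.contains(draws))
        # log-uniform: order-of-magnitude bins are equally occupied
        logs = np.log10(draws[:, 0])
        hist, _ = np.histogram(logs, bins=3, range=(-2, 1))
        assert hist.min() > 0.25 * hist.max()

    def test_round_trip_transform(self):
        prior = cc.default_direct_prior()
        rng = np.random.default_rng(1)
        theta = prior.sample(rng, 10)
        np.testing.assert_allclose(
            prior.to_natural(prior.to_sampled(theta)), theta, rtol=1e-12)

    def test_dict_round_trip(self):
        prior = cc.default_resource_prior()
        again = cc.PriorSpec.from_dict(prior.to_dict())
        assert again.bounds == prior.bounds and again.scales == prior.scales


class TestSamplePosterior:
    def test_point_collapsed_prior_returns_prior(self, truth, core_conditions,
                                                 noisy_core):
        prior = cc.default_direct_prior().collapse_to(truth.to_array())
        s = cc.sample_posterior("direct", noisy_core, core_conditions,
                                prior=prior, n_chains=3, n_iter=200, seed=0,
                                dt=0.01)
        assert np.max(np.abs(s.draws / truth.to_array() - 1.0)) < 1e-6
        assert np.ptp(s.loglik) / abs(s.loglik.mean()) < 1e-4

    def test_reproducible_and_seed_sensitive(self, core_conditions, noisy_core):
        kw = dict(n_chains=3, n_iter=300, dt=0.01)
        a = cc.sample_posterior("direct", noisy_core, core_conditions, seed=1, **kw)
        b = cc.sample_posterior("direct", noisy_core, core_conditions, seed=1, **kw)
        c = cc.sample_posterior("direct", noisy_core, core_conditions, seed=2, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.loglik, b.loglik)
        assert not np.array_equal(a.draws, c.draws)

    def test_draws_respect_prior_support_exactly(self, quick_posterior):
        assert np.all(quick_posterior.prior.contains(quick_posterior.draws))

    def test_loglik_finite_and_consistent(self, quick_posterior, noisy_core,
                                          core_conditions):
        assert np.all(np.isfinite(quick_posterior.loglik))
        eng = cc.LikelihoodEngine("direct", noisy_core, core_conditions, dt=0.01)
        i = int(np.argmax(quick_posterior.loglik))
        recomputed = eng.loglik_many(quick_posterior.draws[i][None, :])[0]
        assert recomputed == pytest.approx(quick_posterior.loglik[i], rel=1e-12)

    def test_needs_three_chains(self, core_conditions, noisy_core):
        with pytest.raises(ValueError, match="chains"):
            cc.sample_posterior("direct", noisy_core, core_conditions,
                                n_chains=2, n_iter=100)

    def test_symmetric_truth_gives_even_posterior_odds(self):
        """With k_WP = k_WW in truth, fraction(k_WP > k_WW) is near 1/2."""
        k = 0.9 / 2e5
        sym = cc.DirectParams(rho_W=1.0, rho_P=1.0, k_WW=k, k_WP=k,
                              k_PW=k, k_PP=k)
        conds = cc.default_conditions("paper_core")
        ds = cc.generate(cc.GeneratorSpec(truth=sym, conditions=conds,
                                          replicates=3, seed=21, dt=0.01))
        s = cc.sample_posterior("direct", ds, conds, n_chains=5, n_iter=8000,
                                seed=3, dt=0.01)
        frac = cc.hypothesis_probability(s, "k_WP > k_WW").fraction
        assert 0.15 < frac < 0.85

    def test_resource_fixes_unobservable_unit_by_default(self, core_conditions):
        p = cc.resource_demo_truth()
        ds = cc.generate(cc.GeneratorSpec(truth=p, conditions=core_conditions,
                                          replicates=1, seed=9, dt=0.01))
        s = cc.sample_posterior("resource", ds, core_conditions, n_chains=3,
                                n_iter=300, seed=0, dt=0.01)
        assert s.fixed == {"R0": 1.0}
        assert np.all(s.param("R0") == 1.0)
        assert s.theta_full().shape[1] == 9

    def test_posterior_file_round_trip(self, quick_posterior, tmp_path):
        path = tmp_path / "posterior.csv"
        quick_posterior.write(path)
        again = cc.PosteriorSamples.read(path, model="direct")
        np.testing.assert_allclose(again.draws, quick_posterior.draws, rtol=1e-15)
        np.testing.assert_allclose(again.loglik, quick_posterior.loglik,
                                   rtol=1e-15)
        assert again.param_names == quick_posterior.param_names
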