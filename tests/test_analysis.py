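import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cocult as cc
from conftest import make_samples

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestRelativeDifference:
    def test_equal_values_give_zero(self):
        assert cc.relative_difference(3.7, 3.7) == 0.0

    def test_threefold_gives_half(self):
        assert cc.relative_difference(2.0, 6.0) == 0.5

    @given(a=positive, b=positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        d = cc.relative_difference(a, b)
        assert d == -cc.relative_difference(b, a)
        assert -1.0 < d < 1.0

    def test_vectorised(self):
        out = cc.relative_difference(np.array([1.0, 2.0]), np.array([3.0, 2.0]))
        np.testing.assert_allclose(out, [0.5, 0.0])

    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (-1.0, 1.0), (1.0, np.inf)])
    def test_rejects_nonpositive_or_nonfinite(self, a, b):
        with pytest.raises(ValueError):
            cc.relative_difference(a, b)


class TestHypothesisProbability:
    def test_all_draws_satisfying_gives_one(self):
        s = make_samples({"rho_W": [0.9, 0.8, 0.7], "rho_P": [1.1, 1.2, 1.3]})
        h = cc.hypothesis_probability(s, "rho_P > rho_W")
        assert h.fraction == 1.0
        assert np.all(h.rel_diff > 0)

    def test_symmetric_draws_give_half(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0.0, 0.1, 4000)
        b = rng.lognormal(0.0, 0.1, 4000)
        s = make_samples({"k_WP": a, "k_WW": b})
        h = cc.hypothesis_probability(s, "k_WP > k_WW")
        assert h.fraction == pytest.approx(0.5, abs=0.05)
        assert h.median_rel_diff() == pytest.approx(0.0, abs=0.02)

    def test_less_than_direction(self):
        s = make_samples({"k_WW": [1.0, 2.0], "k_WP": [3.0, 4.0]})
        h = cc.hypothesis_probability(s, "k_WW < k_WP")
        assert h.fraction == 1.0
        assert np.all(h.rel_diff > 0)

    def test_unknown_parameter_rejected(self, quick_posterior):
        with pytest.raises(ValueError, match="unknown parameter"):
            cc.hypothesis_probability(quick_posterior, "rho_X > rho_W")

    def test_malformed_inequality_rejected(self, quick_posterior):
        with pytest.raises(ValueError, match="inequality"):
            cc.hypothesis_probability(quick_posterior, "rho_P >= rho_W")


class TestPredictionBand:
    def test_identical_draws_collapse_to_single_trajectory(self, truth):
        theta = truth.to_array()
        s = make_samples(
            {n: np.full(5, v) for n, v in zip(truth.names, theta)},
            loglik=np.zeros(5),
        )
        cond = cc.Condition(id="co", W0=4e4, P0=4e4)
        band = cc.prediction_band(s, "direct", cond, dt=0.01)
        assert band.n_retained == 5
        np.testing.assert_array_equal(band.lower_W, band.upper_W)
        np.testing.assert_array_equal(band.lower_W, band.ml_W)

    def test_envelope_contains_ml_trajectory(self, quick_posterior):
        cond = cc.Condition(id="co", W0=4e4, P0=4e4)
        band = cc.prediction_band(quick_posterior, "direct", cond)
        if band.lower_W is None:
            pytest.skip("degenerate band: fewer than 2 retained draws")
        assert np.all(band.lower_W <= band.ml_W + 1e-9)
        assert np.all(band.ml_W <= band.upper_W + 1e-9)
        assert np.all(band.lower_P <= band.ml_P + 1e-9)
        assert np.all(band.ml_P <= band.upper_P + 1e-9)

    def test_single_retained_draw_warns_and_returns_ml_only(self, truth):
        theta = truth.to_array()
        draws = {n: np.array([v, v * 1.5]) for n, v in zip(truth.names, theta)}
        s = make_samples(draws, loglik=np.array([0.0, -1000.0]))
        cond = cc.Condition(id="co", W0=4e4, P0=4e4)
        with pytest.warns(UserWarning, match="fewer than 2"):
            band = cc.prediction_band(s, "direct", cond, dt=0.01)
        assert band.lower_W is None and band.n_retained == 1
        assert band.ml_W.shape == (5,)

    def test_threshold_validation(self, quick_posterior):
        cond = cc.Condition(id="co", W0=4e4, P0=4e4)
        with pytest.raises(ValueError):
            cc.prediction_band(quick_posterior, "direct", cond, threshold=0.0)


class TestRankConditions:
    def candidates(self):
        return [
            cc.Condition(id="a_low", W0=4e4, P0=4e4),
            cc.Condition(id="b_high", W0=9e5, P0=9e5),
        ]

    def test_degenerate_posterior_scores_zero_in_id_order(self, truth):
        s = make_samples(
            {n: np.array([v]) for n, v in zip(truth.names, truth.to_array())},
            loglik=np.zeros(1), n_chains=1,
        )
        ranked = cc.rank_conditions(s, self.candidates(), dt=0.01)
        assert [c.id for c, _ in ranked] == ["a_low", "b_high"]
        assert all(score == 0.0 for _, score in ranked)

    def test_extrapolated_density_scores_higher_for_dispersed_posterior(self,
                                                                        truth):
        # two draws that agree at low density but diverge at high density:
        # same rho, different homotypic competition strengths
        t2 = truth.to_dict()
        t2["k_WW"] *= 3.0
        t2["k_PP"] *= 3.0
        draws = {n: np.array([truth.to_dict()[n], t2[n]])
                 for n in truth.names}
        s = make_samples(draws, loglik=np.zeros(2))
        fitted_like = cc.Condition(id="fitted", W0=1e3, P0=1e3,
                                   sample_days=(0.0, 0.5, 1.0))
        extrapolated = cc.Condition(id="new_dense", W0=5e5, P0=5e5)
        ranked = cc.rank_conditions(s, [fitted_like, extrapolated], dt=0.01)
        assert ranked[0][0].id == "new_dense"
        assert ranked[0][1] > ranked[1][1]

    def test_scores_invariant_to_candidate_order(self, quick_posterior):
        cands = self.candidates()
        r1 = cc.rank_conditions(quick_posterior, cands)
        r2 = cc.rank_conditions(quick_posterior, cands[::-1])
        assert [(c.id, s) for c, s in r1] == [(c.id, s) for c, s in r2]

    def test_empty_candidates_rejected(self, quick_posterior):
        with pytest.raises(ValueError):
            cc.rank_conditions(quick_posterior, [])


class TestCompareModelsLight:
    def test_self_consistency_across_seeds(self, core_conditions, truth):
        """Two fits of the same model with different seeds agree on max loglik."""
        ds = cc.generate(cc.GeneratorSpec(truth=truth,
                                          conditions=core_conditions,
                                          replicates=1, seed=4, dt=0.01))
        fits = [
            cc.sample_posterior("direct", ds, core_conditions, n_chains=5,
                                n_iter=6000, seed=s, dt=0.01)
            for s in (11, 22)
        ]
        gaps = abs(fits[0].loglik.max() - fits[1].loglik.max())
        assert gaps < 5.0
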