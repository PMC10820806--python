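import math

import numpy as np
import pytest
from scipy import stats

import cocult as cc
from cocult import _kernels


def toy_setup(truth):
    """A 3-point toy dataset on one co-culture condition."""
    cond = cc.Condition(id="co", W0=4e4, P0=4e4, sample_days=(0.0, 1.0, 2.0))
    tr = cc.integrate("direct", truth, cc.PopulationState(W=4e4, P=4e4),
                      t_end=2.0, dt=0.01, sample_times=(0.0, 1.0, 2.0))
    rows = []
    offsets = [0.0, 250.0, -400.0]
    for i, day in enumerate((0.0, 1.0, 2.0)):
        rows.append(("co", "r1", day, "W", max(tr.W[i] + offsets[i], 0.0)))
        rows.append(("co", "r1", day, "P", max(tr.P[i] - offsets[i], 0.0)))
    return cond, cc.GrowthDataset.from_records(rows), tr


class TestLogLikelihood:
    def test_matches_hand_summed_gaussian_density(self, truth):
        """Independent oracle: scipy normal log-densities summed by hand."""
        cond, ds, tr = toy_setup(truth)
        expected = 0.0
        model = {("W", d): w for d, w in zip((0.0, 1.0, 2.0), tr.W)}
        model.update({("P", d): p for d, p in zip((0.0, 1.0, 2.0), tr.P)})
        for _, row in ds.frame.iterrows():
            mu = model[(row["species"], row["day"])]
            sigma = math.sqrt(max(mu, 1.0))
            expected += stats.norm.logpdf(row["count"], loc=mu, scale=sigma)
        got = cc.log_likelihood(truth, "direct", ds, [cond], dt=0.01)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_perfect_fit_leaves_only_normalisation(self, truth, core_conditions,
                                                   noisefree_core):
        ll = cc.log_likelihood(truth, "direct", noisefree_core, core_conditions,
                               dt=1e-3)
        eng = cc.LikelihoodEngine("direct", noisefree_core, core_conditions,
                                  dt=1e-3)
        M = eng.model_values(truth.to_array()[None, :])
        x_model = M[0, eng.rec_day, eng.rec_cond, eng.rec_species]
        sigma2 = np.maximum(x_model, 1.0)
        assert ll == pytest.approx(-0.5 * np.sum(np.log(2 * np.pi * sigma2)),
                                   rel=1e-12)

    def test_doubling_replicates_doubles_loglik(self, truth):
        cond, ds, _ = toy_setup(truth)
        doubled = ds.frame.copy()
        doubled["replicate"] = "r2"
        both = cc.GrowthDataset(
            __import__("pandas").concat([ds.frame, doubled], ignore_index=True)
        )
        one = cc.log_likelihood(truth, "direct", ds, [cond], dt=0.01)
        two = cc.log_likelihood(truth, "direct", both, [cond], dt=0.01)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_one_sd_deviation_costs_half_plus_normalisation(self, truth):
        """A point one model-sd off scores -1/2 - log(2 pi mu)/2."""
        cond = cc.Condition(id="w", W0=4e4, P0=0.0, sample_days=(0.0, 1.0))
        tr = cc.integrate("direct", truth, cc.PopulationState(W=4e4, P=0.0),
                          t_end=1.0, dt=0.01, sample_times=(0.0, 1.0))
        mu = tr.W[1]
        ds_exact = cc.GrowthDataset.from_records(
            [("w", "r1", 0.0, "W", 4e4), ("w", "r1", 1.0, "W", mu)])
        ds_off = cc.GrowthDataset.from_records(
            [("w", "r1", 0.0, "W", 4e4),
             ("w", "r1", 1.0, "W", mu + math.sqrt(mu))])
        delta = (cc.log_likelihood(truth, "direct", ds_off, [cond], dt=0.01)
                 - cc.log_likelihood(truth, "direct", ds_exact, [cond], dt=0.01))
        assert delta == pytest.approx(-0.5, rel=1e-9)

    def test_nonfinite_trajectory_returns_minus_inf(self):
        p = cc.ResourceParams(alpha_W=10.0, alpha_P=10.0, delta_W=0.01,
                              delta_P=0.01, gamma_W=1e-9, gamma_P=1e-9,
                              r_W=1e-3, r_P=1e-3, R0=1.0)
        cond = cc.Condition(id="w", W0=1e300, P0=1.0, sample_days=(0.0, 4.0))
        ds = cc.GrowthDataset.from_records(
            [("w", "r1", 0.0, "W", 1e300), ("w", "r1", 4.0, "W", 1e300)])
        with np.errstate(over="ignore", invalid="ignore"):
            assert cc.log_likelihood(p, "resource", ds, [cond], dt=0.01) == -np.inf

    def test_deterministic_given_inputs(self, truth, core_conditions, noisy_core):
        a = cc.log_likelihood(truth, "direct", noisy_core, core_conditions, dt=0.01)
        b = cc.log_likelihood(truth, "direct", noisy_core, core_conditions, dt=0.01)
        assert a == b

    def test_empty_dataset_rejected(self, core_conditions):
        with pytest.raises(ValueError, match="empty"):
            cc.LikelihoodEngine("direct", cc.GrowthDataset.from_records([]),
                                core_conditions)


class TestKernelEquivalence:
    @pytest.mark.skipif(not _kernels.HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_paths_agree_bitwise(self, truth, core_conditions,
                                                 noisy_core):
        eng = cc.LikelihoodEngine("direct", noisy_core, core_conditions, dt=0.01)
        theta = np.vstack([truth.to_array(), truth.to_array() * 1.1])
        fast = eng.model_values(theta)
        _kernels.HAVE_NUMBA = False
        try:
            slow = eng.model_values(theta)
        finally:
            _kernels.HAVE_NUMBA = True
        np.testing.assert_array_equal(fast, slow)

    @pytest.mark.skipif(not _kernels.HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_paths_agree_with_intervention(self, truth):
        cond = cc.Condition(
            id="dox", W0=4e4, P0=4e4,
            schedule=cc.InterventionSchedule(t_dox=2.0, mode="full"))
        ds = cc.GrowthDataset.from_records(
            [("dox", "r1", d, s, 1000.0) for d in (0.0, 2.0, 4.0)
             for s in ("W", "P")])
        eng = cc.LikelihoodEngine("direct", ds, [cond], dt=0.01)
        theta = truth.to_array()[None, :]
        fast = eng.model_values(theta)
        _kernels.HAVE_NUMBA = False
        try:
            slow = eng.model_values(theta)
        finally:
            _kernels.HAVE_NUMBA = True
        np.testing.assert_array_equal(fast, slow)

    @pytest.mark.skipif(not _kernels.HAVE_NUMBA, reason="numba not installed")
    def test_resource_paths_agree(self, core_conditions):
        p = cc.resource_demo_truth()
        ds = cc.generate(cc.GeneratorSpec(truth=p, conditions=core_conditions,
                                          replicates=1, seed=3, dt=0.01))
        eng = cc.LikelihoodEngine("resource", ds, core_conditions, dt=0.01)
        theta = p.to_array()[None, :]
        fast = eng.model_values(theta)
        _kernels.HAVE_NUMBA = False
        try:
            slow = eng.model_values(theta)
        finally:
            _kernels.HAVE_NUMBA = True
        np.testing.assert_array_equal(fast, slow)
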