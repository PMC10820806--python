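import numpy as np
import pytest

import cocult as cc


@pytest.fixture(scope="session")
def truth():
    return cc.recovery_truth()


@pytest.fixture(scope="session")
def core_conditions():
    return cc.default_conditions("paper_core")


@pytest.fixture(scope="session")
def noisefree_core(truth, core_conditions):
    """Noise-free dataset lying exactly on the direct-model trajectories."""
    spec = cc.GeneratorSpec(
        truth=truth, conditions=core_conditions, replicates=1, noise="none", seed=0
    )
    return cc.generate(spec)


@pytest.fixture(scope="session")
def noisy_core(truth, core_conditions):
    spec = cc.GeneratorSpec(
        truth=truth, conditions=core_conditions, replicates=3, seed=123
    )
    return cc.generate(spec)


@pytest.fixture(scope="session")
def quick_posterior(noisy_core, core_conditions):
    """A small but genuine posterior fit used by downstream-analysis tests."""
    return cc.sample_posterior(
        "direct",
        noisy_core,
        core_conditions,
        n_chains=5,
        n_iter=4000,
        seed=5,
        dt=0.01,
    )


def make_samples(draw_dict, loglik=None, n_chains=2, model="direct"):
    """Hand-built PosteriorSamples for analysis-level unit tests."""
    names = tuple(draw_dict)
    draws = np.column_stack([np.asarray(v, dtype=float) for v in draw_dict.values()])
    n = len(draws)
    if loglik is None:
        loglik = np.zeros(n)
    chain = np.arange(n) % n_chains
    prior = cc.PriorSpec(
        bounds={k: (1e-12, 1e12) for k in names},
        scales={k: "log10" for k in names},
    )
    return cc.PosteriorSamples(
        draws=draws,
        loglik=np.asarray(loglik, dtype=float),
        chain=chain,
        iteration=np.arange(n),
        param_names=names,
        model=model,
        prior=prior,
        dt=0.01,
    )
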