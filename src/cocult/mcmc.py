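"""DREAM-style MCMC posterior sampling and convergence diagnostics.

The sampler is a differential-evolution Metropolis with a growing archive of
past states (DE-MC(Z)): each of several parallel chains proposes

    z* = z + gamma * (z_r1 - z_r2) + e,    e ~ N(0, eps^2 I)

where ``z_r1, z_r2`` are distinct states drawn from the shared archive of
past chain states, ``gamma = 2.38 / sqrt(2 d)`` for ordinary moves with an
occasional ``gamma = 1`` mode-hopping move.  Proposals are evaluated on the
prior's sampling scale (log10 for the default log-uniform priors) where the
posterior is simply the likelihood restricted to the prior box.

Convergence is assessed with the Gelman-Rubin potential-scale-reduction
factor across chains, with the conventional threshold R-hat < 1.2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .data import Condition, GrowthDataset
from .likelihood import DEFAULT_FIT_DT, LikelihoodEngine
from .params import DirectParams, ResourceParams
from .priors import PriorSpec, default_direct_prior, default_resource_prior

__all__ = [
    "PosteriorSamples",
    "GelmanRubinResult",
    "ConvergenceError",
    "sample_posterior",
    "gelman_rubin",
    "RHAT_THRESHOLD",
]

RHAT_THRESHOLD = 1.2


class ConvergenceError(RuntimeError):
    """Raised when the sampler cannot produce usable chains."""


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws with per-draw log-likelihood and chain labels.

    ``draws`` is an (n, d) natural-scale matrix with columns ``param_names``;
    ``loglik``, ``chain`` and ``iteration`` are aligned length-n vectors.
    """

    draws: np.ndarray
    loglik: np.ndarray
    chain: np.ndarray
    iteration: np.ndarray
    param_names: tuple
    model: str
    prior: PriorSpec
    dt: float = DEFAULT_FIT_DT
    seed: Optional[int] = None
    n_chains: int = 0
    n_iter: int = 0
    acceptance_rate: float = float("nan")
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        self.loglik = np.asarray(self.loglik, dtype=float)
        self.chain = np.asarray(self.chain)
        self.iteration = np.asarray(self.iteration)
        n = len(self.draws)
        if not (len(self.loglik) == len(self.chain) == len(self.iteration) == n):
            raise ValueError("draws, loglik, chain, iteration must be aligned")
        if self.n_chains == 0:
            self.n_chains = len(np.unique(self.chain))

    def __len__(self) -> int:
        return len(self.draws)

    def param(self, name: str) -> np.ndarray:
        """Natural-scale draws of one parameter (constant if held fixed)."""
        if name in self.fixed:
            return np.full(len(self), float(self.fixed[name]))
        try:
            j = self.param_names.index(name)
        except ValueError:
            raise ValueError(
                f"unknown parameter {name!r}; have {self.param_names} "
                f"plus fixed {tuple(self.fixed)}"
            ) from None
        return self.draws[:, j]

    def theta_full(self, idx=None) -> np.ndarray:
        """Draws as full model parameter matrices, fixed values included."""
        cls = DirectParams if self.model == "direct" else ResourceParams
        sel = self.draws if idx is None else np.atleast_2d(self.draws[idx])
        full = np.empty((len(sel), len(cls.names)))
        for j, name in enumerate(cls.names):
            if name in self.fixed:
                full[:, j] = float(self.fixed[name])
            else:
                full[:, j] = sel[:, self.param_names.index(name)]
        return full

    def map_estimate(self):
        """Maximum-likelihood draw as a parameter object."""
        cls = DirectParams if self.model == "direct" else ResourceParams
        return cls.from_array(self.theta_full(int(np.argmax(self.loglik)))[0])

    def by_chain_sampled(self) -> np.ndarray:
        """Draws on the sampling scale, shaped (n_chains, n_per_chain, d).

        Chains of unequal length are truncated to the shortest with a
        warning.
        """
        labels = np.unique(self.chain)
        per = [self.prior.to_sampled(self.draws[self.chain == c]) for c in labels]
        n_min = min(len(p) for p in per)
        if any(len(p) != n_min for p in per):
            warnings.warn("chains of unequal length; truncating to shortest")
            per = [p[:n_min] for p in per]
        return np.stack(per)

    def credible_interval(self, name: str, level: float = 0.95):
        lo = (1.0 - level) / 2.0
        x = self.param(name)
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df.insert(0, "iteration", self.iteration)
        df.insert(0, "chain", self.chain)
        df["loglik"] = self.loglik
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read(cls, path, model: str, prior: Optional[PriorSpec] = None,
             dt: float = DEFAULT_FIT_DT) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = tuple(
            c for c in df.columns if c not in ("chain", "iteration", "loglik")
        )
        if prior is None:
            prior = (
                default_direct_prior() if model == "direct"
                else default_resource_prior()
            )
        return cls(
            draws=df[list(names)].to_numpy(),
            loglik=df["loglik"].to_numpy(),
            chain=df["chain"].to_numpy(),
            iteration=df["iteration"].to_numpy(),
            param_names=names,
            model=model,
            prior=prior,
            dt=dt,
        )

    def summary(self, level: float = 0.95) -> dict:
        """Per-parameter medians, credible intervals and R-hat."""
        gr = gelman_rubin(self)
        out = {}
        for name in self.param_names:
            lo, hi = self.credible_interval(name, level)
            out[name] = {
                "median": float(np.median(self.param(name))),
                "ci_lower": lo,
                "ci_upper": hi,
                "rhat": gr.rhat[name],
            }
        return {
            "model": self.model,
            "n_draws": len(self),
            "n_chains": int(self.n_chains),
            "max_loglik": float(np.max(self.loglik)),
            "converged": gr.converged,
            "parameters": out,
        }


@dataclass(frozen=True)
class GelmanRubinResult:
    rhat: Dict[str, float]
    converged: bool
    threshold: float = RHAT_THRESHOLD

    def max(self) -> float:
        return max(self.rhat.values())


def _psrf(chains: np.ndarray) -> float:
    """Classic (non-split) potential scale reduction for an (m, n) array."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(math.sqrt(v_hat / W))


def gelman_rubin(
    samples: PosteriorSamples, threshold: float = RHAT_THRESHOLD
) -> GelmanRubinResult:
    """Per-parameter Gelman-Rubin R-hat across chains (sampling scale).

    Requires at least two chains with at least ten draws each; chains of
    unequal length are truncated to the shortest.  The convergence flag is
    ``all R-hat < threshold`` (default 1.2).
    """
    z = samples.by_chain_sampled()  # (m, n, d)
    m, n, d = z.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires >= 10 draws per chain")
    rhat = {
        name: _psrf(z[:, :, j]) for j, name in enumerate(samples.param_names)
    }
    return GelmanRubinResult(
        rhat=rhat,
        converged=all(v < threshold for v in rhat.values()),
        threshold=threshold,
    )


def sample_posterior(
    model: str,
    dataset: GrowthDataset,
    conditions: Sequence[Condition],
    prior: Optional[PriorSpec] = None,
    n_chains: int = 5,
    n_iter: int = 2500,
    seed: int = 0,
    dt: float = DEFAULT_FIT_DT,
    sigma2_floor: float = 1.0,
    burn_frac: float = 0.5,
    jump_prob: float = 0.1,
    archive_thin: int = 10,
    eps: float = 1e-6,
    outlier_every: int = 100,
    outlier_ll_gap: float = 10.0,
    fixed: Optional[dict] = None,
) -> PosteriorSamples:
    """Sample the posterior with the DE-MC(Z) sampler.

    Chains start from independent prior draws (over-dispersed start, as the
    Gelman-Rubin diagnostic assumes); the first ``burn_frac`` of every chain
    is discarded.  Fully reproducible given ``seed``.
    """
    if model not in ("direct", "resource"):
        raise ValueError(f"model must be 'direct' or 'resource', got {model!r}")
    if n_chains < 3:
        raise ValueError("need at least 3 chains for convergence diagnostics")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not (0.0 <= burn_frac < 1.0):
        raise ValueError("burn_frac must be in [0, 1)")
    if prior is None:
        prior = default_direct_prior() if model == "direct" else default_resource_prior()
    expected = DirectParams.names if model == "direct" else ResourceParams.names
    fixed = dict(fixed or {})
    missing = [n for n in expected if n not in prior.names and n not in fixed]
    if missing == ["R0"] and model == "resource":
        # the resource unit is unobservable; pin it by convention
        fixed["R0"] = 1.0
        missing = []
    if missing:
        raise ValueError(
            f"prior/fixed must cover parameters {expected}; missing {missing}"
        )
    extra = [n for n in prior.names if n not in expected]
    if extra or any(n not in expected for n in fixed):
        raise ValueError(f"unknown parameters in prior/fixed for model {model!r}")
    sampled_idx = [expected.index(n) for n in prior.names]

    engine = LikelihoodEngine(model, dataset, conditions, dt, sigma2_floor)

    def loglik_of(nat: np.ndarray) -> np.ndarray:
        full = np.empty((nat.shape[0], len(expected)))
        for name, value in fixed.items():
            full[:, expected.index(name)] = float(value)
        full[:, sampled_idx] = nat
        return engine.loglik_many(full)

    rng = np.random.default_rng(seed)
    d = prior.dim
    m = n_chains

    n_seed_archive = max(10 * d, 2 * m)
    cap = n_seed_archive + m * (n_iter // archive_thin + 2)
    Z = np.empty((cap, d))
    Z[:n_seed_archive] = prior.to_sampled(prior.sample(rng, n_seed_archive))
    n_arch = n_seed_archive

    x = Z[:m].copy()
    lp = loglik_of(prior.to_natural(x))

    out_z = np.empty((n_iter, m, d))
    out_lp = np.empty((n_iter, m))
    accepted = 0
    burn_iters = int(burn_frac * n_iter)

    crossover_menu = np.array([1.0 / 3.0, 2.0 / 3.0, 1.0])
    lo_b, hi_b = prior._scaled_bounds()
    eps_vec = eps * (hi_b - lo_b)  # jitter scaled to each dimension's extent

    for it in range(n_iter):
        # archive indices: distinct pair per chain
        r1 = rng.integers(0, n_arch, size=m)
        r2 = rng.integers(0, n_arch - 1, size=m)
        r2[r2 >= r1] += 1
        # DREAM-style moves: occasional full-dimension gamma=1 mode jumps,
        # otherwise subspace updates (random crossover mask) with jittered
        # gamma scaled to the updated dimension count
        jump = rng.random(m) < jump_prob
        cr = rng.choice(crossover_menu, size=m)
        mask = rng.random((m, d)) < cr[:, None]
        none_on = ~mask.any(axis=1)
        if np.any(none_on):
            mask[none_on, rng.integers(0, d, size=int(none_on.sum()))] = True
        mask[jump] = True
        d_eff = mask.sum(axis=1)
        gamma = 2.38 / np.sqrt(2.0 * d_eff) * rng.uniform(0.5, 1.5, size=m)
        gamma[jump] = 1.0
        props = x + mask * (
            gamma[:, None] * (Z[r1] - Z[r2])
            + eps_vec * rng.standard_normal((m, d))
        )

        lp_prop = np.full(m, -np.inf)
        ok = prior.in_support_sampled(props)
        if np.any(ok):
            lp_prop[ok] = loglik_of(prior.to_natural(props[ok]))
        accept = np.log(rng.random(m)) < (lp_prop - lp)
        x[accept] = props[accept]
        lp[accept] = lp_prop[accept]
        accepted += int(accept.sum())

        out_z[it] = x
        out_lp[it] = lp
        if (it + 1) % archive_thin == 0:
            Z[n_arch : n_arch + m] = x
            n_arch += m

        # outlier-chain correction (burn-in only), as in the DREAM family's
        # standard handling: chains marooned on a far-worse likelihood
        # plateau (IQR rule) or in a mode whose posterior mass is negligible
        # relative to the best chain (absolute log-likelihood gap) are moved
        # to the best chain's state
        if outlier_every and it < burn_iters and (it + 1) % outlier_every == 0:
            half = max(1, (it + 1) // 2)
            mean_lp = out_lp[it + 1 - half : it + 1].mean(axis=0)
            q1, q3 = np.percentile(mean_lp, [25, 75])
            outliers = (mean_lp < q1 - 2.0 * (q3 - q1)) | (
                mean_lp < mean_lp.max() - outlier_ll_gap
            )
            if np.any(outliers) and not np.all(outliers):
                best = int(np.argmax(lp))
                x[outliers] = x[best]
                lp[outliers] = lp[best]

    burn = burn_iters
    if accepted == 0:
        raise ConvergenceError(
            "no accepted moves; likelihood may be degenerate "
            f"(final log-posteriors: {out_lp[-1]})"
        )

    kept_z = out_z[burn:]  # (n_kept, m, d)
    kept_lp = out_lp[burn:]
    n_kept = kept_z.shape[0]
    draws = prior.to_natural(kept_z.transpose(1, 0, 2).reshape(m * n_kept, d))
    loglik = kept_lp.T.reshape(m * n_kept)
    chain = np.repeat(np.arange(m), n_kept)
    iteration = np.tile(np.arange(burn, n_iter), m)

    return PosteriorSamples(
        draws=draws,
        loglik=loglik,
        chain=chain,
        iteration=iteration,
        param_names=tuple(prior.names),
        model=model,
        prior=prior,
        dt=dt,
        seed=seed,
        n_chains=m,
        n_iter=n_iter,
        acceptance_rate=accepted / (n_iter * m),
        fixed=fixed,
    )
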