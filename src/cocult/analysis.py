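"""Posterior hypothesis tests, prediction bands, model comparison, design.

These operate on :class:`~cocult.mcmc.PosteriorSamples` and provide the
downstream analyses: posterior fractions for parameter inequalities,
the bounded relative-difference statistic, >90%-of-max-likelihood prediction
envelopes, log-likelihood model comparison between the direct and resource
models, and a posterior-predictive-variance ranking of candidate plating
conditions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import Condition, GrowthDataset
from .likelihood import DEFAULT_FIT_DT, LikelihoodEngine
from .mcmc import (
    ConvergenceError,
    GelmanRubinResult,
    PosteriorSamples,
    RHAT_THRESHOLD,
    gelman_rubin,
    sample_posterior,
)
from .priors import PriorSpec, default_direct_prior, default_resource_prior

__all__ = [
    "relative_difference",
    "hypothesis_probability",
    "HypothesisResult",
    "prediction_band",
    "PredictionBand",
    "compare_models",
    "ModelComparison",
    "rank_conditions",
]


def relative_difference(p1, p2):
    """Bounded relative difference ``(p2 - p1) / (p2 + p1)`` in (-1, 1).

    Both inputs must be strictly positive (scalars or arrays).  The statistic
    is antisymmetric, zero for equal values, and 0.5 when p2 = 3 p1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(p1 <= 0) or np.any(p2 <= 0) or not (
        np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))
    ):
        raise ValueError("relative_difference requires strictly positive inputs")
    out = (p2 - p1) / (p2 + p1)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HypothesisResult:
    """Posterior support for a parameter inequality.

    ``fraction`` is the share of posterior draws satisfying the inequality;
    ``rel_diff`` is the per-draw relative-difference distribution, oriented
    so positive values correspond to draws satisfying the inequality.
    """

    inequality: str
    fraction: float
    rel_diff: np.ndarray

    def median_rel_diff(self) -> float:
        return float(np.median(self.rel_diff))


_INEQ_RE = re.compile(r"^\s*(\w+)\s*([<>])\s*(\w+)\s*$")


def hypothesis_probability(
    samples: PosteriorSamples, inequality: str
) -> HypothesisResult:
    """Fraction of posterior draws satisfying e.g. ``"rho_P > rho_W"``.

    Also returns the posterior distribution of the relative difference
    between the two parameters, oriented so that positive values agree with
    the stated inequality.
    """
    match = _INEQ_RE.match(inequality)
    if not match:
        raise ValueError(
            f"inequality must look like 'a > b' or 'a < b', got {inequality!r}"
        )
    left, op, right = match.groups()
    a = samples.param(left)
    b = samples.param(right)
    if op == ">":
        fraction = float(np.mean(a > b))
        rel = relative_difference(b, a)  # positive when a > b
    else:
        fraction = float(np.mean(a < b))
        rel = relative_difference(a, b)  # positive when a < b
    return HypothesisResult(inequality=inequality, fraction=fraction, rel_diff=rel)


@dataclass(frozen=True)
class PredictionBand:
    """Pointwise trajectory envelope over near-maximum-likelihood draws.

    ``ml_W``/``ml_P`` is the maximum-likelihood trajectory; the lower/upper
    envelopes are ``None`` when fewer than two draws passed the likelihood
    threshold.
    """

    times: np.ndarray
    ml_W: np.ndarray
    ml_P: np.ndarray
    lower_W: Optional[np.ndarray]
    upper_W: Optional[np.ndarray]
    lower_P: Optional[np.ndarray]
    upper_P: Optional[np.ndarray]
    n_retained: int
    threshold: float


def _simulate_draws(
    model: str,
    thetas: np.ndarray,
    condition: Condition,
    dt: float,
    times: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trajectories of many parameter draws for one condition.

    Returns (W, P) arrays of shape (n_times, n_draws).  Implemented through
    the batch likelihood engine with a one-condition pseudo-dataset.
    """
    cond = Condition(
        id=condition.id,
        W0=condition.W0,
        P0=condition.P0,
        sample_days=tuple(times),
        schedule=condition.schedule,
    )
    anchor = GrowthDataset.from_records(
        [(cond.id, "r1", cond.sample_days[0], "W", 0.0)]
    )
    engine = LikelihoodEngine(model, anchor, [cond], dt=dt)
    M = engine.model_values(np.atleast_2d(thetas))  # (m, n_times, 1, 2)
    return M[:, :, 0, 0].T, M[:, :, 0, 1].T


def prediction_band(
    samples: PosteriorSamples,
    model: str,
    condition: Condition,
    threshold: float = 0.90,
    dt: Optional[float] = None,
    times: Optional[Sequence[float]] = None,
) -> PredictionBand:
    """Envelope of trajectories with likelihood above ``threshold * L_max``.

    Draws with log-likelihood >= ``log L_max + log(threshold)`` are
    simulated for ``condition``; the band is their pointwise min/max for
    both species, and always contains the maximum-likelihood trajectory.
    With fewer than two retained draws a warning is issued and only the
    maximum-likelihood trajectory is returned.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    dt = samples.dt if dt is None else dt
    if times is None:
        times = np.asarray(condition.sample_days, dtype=float)
    else:
        times = np.asarray(times, dtype=float)

    cutoff = np.max(samples.loglik) + np.log(threshold)
    retained = samples.loglik >= cutoff
    n_ret = int(retained.sum())
    ml_theta = samples.draws[int(np.argmax(samples.loglik))]
    ml_W, ml_P = _simulate_draws(model, ml_theta[None, :], condition, dt, times)

    if n_ret < 2:
        warnings.warn(
            "fewer than 2 draws above the likelihood threshold; "
            "returning the maximum-likelihood trajectory only "
            "(consider widening the threshold)"
        )
        return PredictionBand(
            times=times,
            ml_W=ml_W[:, 0],
            ml_P=ml_P[:, 0],
            lower_W=None,
            upper_W=None,
            lower_P=None,
            upper_P=None,
            n_retained=n_ret,
            threshold=threshold,
        )

    W, P = _simulate_draws(model, samples.draws[retained], condition, dt, times)
    return PredictionBand(
        times=times,
        ml_W=ml_W[:, 0],
        ml_P=ml_P[:, 0],
        lower_W=W.min(axis=1),
        upper_W=W.max(axis=1),
        lower_P=P.min(axis=1),
        upper_P=P.max(axis=1),
        n_retained=n_ret,
        threshold=threshold,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Posterior log-likelihood distributions of both models on one dataset."""

    loglik_direct: np.ndarray
    loglik_resource: np.ndarray
    rhat_direct: GelmanRubinResult
    rhat_resource: GelmanRubinResult

    @property
    def max_direct(self) -> float:
        return float(np.max(self.loglik_direct))

    @property
    def max_resource(self) -> float:
        return float(np.max(self.loglik_resource))

    @property
    def delta_max(self) -> float:
        """Maximum log-likelihood of direct minus resource."""
        return self.max_direct - self.max_resource

    @property
    def winner(self) -> str:
        return "direct" if self.delta_max > 0 else "resource"


def compare_models(
    dataset: GrowthDataset,
    conditions: Sequence[Condition],
    priors: Optional[Dict[str, PriorSpec]] = None,
    seed: int = 0,
    n_chains: int = 5,
    n_iter=2500,
    dt: float = DEFAULT_FIT_DT,
    sigma2_floor: float = 1.0,
    rhat_threshold: float = RHAT_THRESHOLD,
    max_retries: int = 0,
    return_samples: bool = False,
):
    """Fit both models to the same dataset and compare log-likelihoods.

    Both fits use the identical likelihood definition; the better-fitting
    model is the one with the higher maximum log-likelihood over posterior
    draws.  If either fit fails the Gelman-Rubin check the comparison is
    refused with a :class:`ConvergenceError` carrying the diagnostics.

    ``n_iter`` may be an int or a ``{'direct': ..., 'resource': ...}``
    mapping — the resource posterior typically needs longer chains than the
    six-parameter direct one.  ``max_retries`` refits an unconverged model
    with doubled chain length and a fresh derived seed before giving up;
    the convergence gate itself is unchanged.
    """
    priors = priors or {}
    if not isinstance(n_iter, dict):
        n_iter = {"direct": int(n_iter), "resource": int(n_iter)}
    ss = np.random.SeedSequence(seed)

    fits = {}
    gr = {}
    for model, model_ss in zip(("direct", "resource"), ss.spawn(2)):
        prior = priors.get(model) or (
            default_direct_prior() if model == "direct" else default_resource_prior()
        )
        iters = n_iter[model]
        for attempt_ss in model_ss.spawn(max_retries + 1):
            fit_seed = int(attempt_ss.generate_state(1)[0] % (2**31))
            fits[model] = sample_posterior(
                model,
                dataset,
                conditions,
                prior=prior,
                n_chains=n_chains,
                n_iter=iters,
                seed=fit_seed,
                dt=dt,
                sigma2_floor=sigma2_floor,
            )
            gr[model] = gelman_rubin(fits[model], threshold=rhat_threshold)
            if gr[model].converged:
                break
            iters *= 2
    bad = [m for m in fits if not gr[m].converged]
    if bad:
        detail = {m: gr[m].rhat for m in bad}
        raise ConvergenceError(
            f"refusing model comparison; unconverged fits (R-hat >= "
            f"{rhat_threshold}): {detail}"
        )
    comparison = ModelComparison(
        loglik_direct=fits["direct"].loglik,
        loglik_resource=fits["resource"].loglik,
        rhat_direct=gr["direct"],
        rhat_resource=gr["resource"],
    )
    if return_samples:
        return comparison, fits
    return comparison


def rank_conditions(
    samples: PosteriorSamples,
    candidates: Sequence[Condition],
    dt: Optional[float] = None,
    max_draws: int = 200,
) -> List[Tuple[Condition, float]]:
    """Rank candidate plating conditions by expected informativeness.

    The score of a candidate is the total, over its sampling days and both
    species, of the variance across posterior draws of the predicted counts
    (posterior-predictive disagreement): conditions whose outcome the current
    posterior cannot pin down are the most informative to run next.  Returns
    (condition, score) pairs in descending score order, ties broken by
    condition id.
    """
    if len(samples) == 0:
        raise ValueError("posterior is empty")
    if not candidates:
        raise ValueError("no candidate conditions supplied")
    dt = samples.dt if dt is None else dt
    n = len(samples)
    idx = np.unique(np.linspace(0, n - 1, min(max_draws, n)).astype(int))
    thetas = samples.draws[idx]

    scored = []
    for cond in candidates:
        times = np.asarray(cond.sample_days, dtype=float)
        W, P = _simulate_draws(samples.model, thetas, cond, dt, times)
        score = float(W.var(axis=1).sum() + P.var(axis=1).sum())
        scored.append((cond, score))
    scored.sort(key=lambda cs: (-cs[1], cs[0].id))
    return scored
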