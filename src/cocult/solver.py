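"""Fixed-step explicit forward Euler integration of the competition ODEs.

The integrator advances ``x <- x + dt * f(x)`` on a uniform grid that is
constructed to contain every requested sample time exactly (``dt`` must divide
the inter-sample spacing), so no interpolation convention is needed.  Any
population component driven below zero by a step is clamped to zero: counts
are non-negative by definition.

Besides the single-trajectory :func:`integrate`, the module provides
vectorised batch kernels that advance many wells (and many parameter vectors)
simultaneously; the likelihood machinery is built on those.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    DirectParams,
    InterventionSchedule,
    PopulationState,
    ResourceParams,
    params_at_time,
)

__all__ = [
    "Trajectory",
    "NumericalBlowupError",
    "integrate",
    "logistic_closed_form",
    "DEFAULT_DT",
]

log = logging.getLogger(__name__)

DEFAULT_DT = 1e-3  # days; logistic-oracle relative error < 1e-3 over 4 days

_GRID_RTOL = 1e-9


class NumericalBlowupError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"non-finite state during integration at t = {t:g} days")


@dataclass(frozen=True)
class Trajectory:
    """Populations sampled along an integrated trajectory.

    ``times`` are strictly increasing days starting at the condition's t = 0;
    ``W`` and ``P`` are cell counts at those times; ``R`` is the remaining
    resource (resource model only, else ``None``).
    """

    times: np.ndarray
    W: np.ndarray
    P: np.ndarray
    R: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (time_day, species, value)."""
        parts = [
            pd.DataFrame({"time_day": self.times, "species": "W", "value": self.W}),
            pd.DataFrame({"time_day": self.times, "species": "P", "value": self.P}),
        ]
        if self.R is not None:
            parts.append(
                pd.DataFrame({"time_day": self.times, "species": "R", "value": self.R})
            )
        return pd.concat(parts, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def logistic_closed_form(W0: float, rho: float, k: float, t) -> float:
    """Closed-form single-species logistic solution, the homotypic limit.

    Returns ``K*W0*exp(rho*t) / (K + W0*(exp(rho*t) - 1))`` with carrying
    capacity ``K = rho / k``.  Serves as the analytic oracle for the Euler
    scheme.
    """
    if W0 < 0 or not math.isfinite(W0):
        raise ValueError(f"W0 must be >= 0 and finite, got {W0!r}")
    if rho <= 0 or k <= 0:
        raise ValueError("rho and k must be strictly positive")
    K = rho / k
    e = np.exp(rho * np.asarray(t, dtype=float))
    return K * W0 * e / (K + W0 * (e - 1.0))


def _steps_for(t: float, dt: float, what: str) -> int:
    n = t / dt
    n_round = round(n)
    if abs(n - n_round) > _GRID_RTOL * max(1.0, abs(n)):
        raise ValueError(f"dt = {dt!r} must divide {what} = {t!r} exactly")
    return int(n_round)


def _segment_steps(
    schedule: Optional[InterventionSchedule], dt: float, n_steps: int
) -> Optional[int]:
    """Step index from which switched parameters apply (left-continuous)."""
    if schedule is None or schedule.t_dox is None:
        return None
    # a t_dox on the grid takes effect from that step onward
    s = int(math.ceil(schedule.t_dox / dt - _GRID_RTOL))
    return min(max(s, 0), n_steps)


def integrate(
    model: str,
    params,
    initial: PopulationState,
    t_end: float,
    dt: float = DEFAULT_DT,
    sample_times: Optional[Sequence[float]] = None,
    schedule: Optional[InterventionSchedule] = None,
) -> Trajectory:
    """Integrate one well of either model and sample at requested times.

    Parameters
    ----------
    model : {'direct', 'resource'}
    params : DirectParams or ResourceParams matching ``model``.
    initial : starting state (``R`` defaults to ``params.R0`` for the
        resource model when not given).
    t_end : final time, days.
    dt : Euler step, days; must divide ``t_end`` and every sample time.
    sample_times : days at which to report the state; default = every grid
        point.
    schedule : optional doxycycline intervention (direct model only).
    """
    if model not in ("direct", "resource"):
        raise ValueError(f"model must be 'direct' or 'resource', got {model!r}")
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError(f"dt must be > 0, got {dt!r}")
    if t_end < 0 or not math.isfinite(t_end):
        raise ValueError(f"t_end must be >= 0, got {t_end!r}")
    if model == "resource" and schedule is not None:
        raise ValueError("interventions are defined for the direct model only")
    if model == "direct" and not isinstance(params, DirectParams):
        raise TypeError("direct model requires DirectParams")
    if model == "resource" and not isinstance(params, ResourceParams):
        raise TypeError("resource model requires ResourceParams")

    n_steps = _steps_for(t_end, dt, "t_end")
    if sample_times is None:
        sample_steps = np.arange(n_steps + 1)
    else:
        st = np.asarray(sample_times, dtype=float)
        if st.size == 0:
            raise ValueError("sample_times must be non-empty")
        if np.any(st < 0) or np.any(st > t_end + _GRID_RTOL):
            raise ValueError("sample_times must lie within [0, t_end]")
        sample_steps = np.array([_steps_for(t, dt, f"sample time {t}") for t in st])
        if np.any(np.diff(sample_steps) <= 0):
            raise ValueError("sample_times must be strictly increasing")

    times = sample_steps * dt

    if model == "direct":
        W, P = _euler_direct_batch(
            params,
            np.array([initial.W]),
            np.array([initial.P]),
            dt,
            n_steps,
            sample_steps,
            schedule=schedule,
        )
        _check_finite(W, P, times=times)
        return Trajectory(times=times, W=W[:, 0], P=P[:, 0])

    R0 = initial.R if initial.R is not None else params.R0
    W, P, R = _euler_resource_batch(
        params,
        np.array([initial.W]),
        np.array([initial.P]),
        np.array([R0]),
        dt,
        n_steps,
        sample_steps,
    )
    _check_finite(W, P, R, times=times)
    return Trajectory(times=times, W=W[:, 0], P=P[:, 0], R=R[:, 0])


def _check_finite(*sampled, times):
    for arr in sampled:
        bad_time = ~np.isfinite(arr).reshape(arr.shape[0], -1).all(axis=1)
        if np.any(bad_time):
            raise NumericalBlowupError(float(times[int(np.argmax(bad_time))]))


# ---------------------------------------------------------------------------
# Vectorised batch kernels
#
# State arrays have an arbitrary leading shape (wells, or theta x wells);
# parameters are scalars or arrays broadcastable against that shape.  The
# kernels record the state at the requested step indices and clamp negative
# excursions to zero after every step.


def _direct_param_tuple(params: DirectParams):
    return (
        params.rho_W,
        params.rho_P,
        params.k_WW,
        params.k_WP,
        params.k_PW,
        params.k_PP,
    )


def _euler_direct_batch(
    params,
    W0,
    P0,
    dt,
    n_steps,
    sample_steps,
    schedule: Optional[InterventionSchedule] = None,
    param_arrays=None,
    switched_arrays=None,
    switch_step: Optional[int] = None,
):
    """Advance the direct model for a batch of wells.

    ``param_arrays`` (tuple of 6 broadcastable arrays, order as
    ``DirectParams.names``) overrides ``params`` for vectorised-theta use;
    ``switched_arrays`` likewise provides post-intervention parameters, and
    ``switch_step`` (grid index) may replace ``schedule``.
    """
    if param_arrays is None:
        param_arrays = _direct_param_tuple(params)
        if schedule is not None and schedule.t_dox is not None:
            switched_arrays = _direct_param_tuple(
                params_at_time(params, schedule, schedule.t_dox)
            )
    if switch_step is None:
        switch_step = _segment_steps(schedule, dt, n_steps)
    if switched_arrays is None:
        switch_step = None

    W, P = np.broadcast_arrays(
        np.asarray(W0, dtype=float), np.asarray(P0, dtype=float)
    )
    W, P = W.copy(), P.copy()

    out_W = np.empty((len(sample_steps),) + W.shape)
    out_P = np.empty_like(out_W)
    sample_set = {int(s): i for i, s in enumerate(sample_steps)}

    rho_W, rho_P, k_WW, k_WP, k_PW, k_PP = param_arrays
    clamped = 0
    for step in range(n_steps + 1):
        if step in sample_set:
            i = sample_set[step]
            out_W[i] = W
            out_P[i] = P
        if step == n_steps:
            break
        if switch_step is not None and step >= switch_step:
            rho_W, rho_P, k_WW, k_WP, k_PW, k_PP = switched_arrays
            switch_step = None  # apply once; arrays stay switched
        dW = W * (rho_W - k_WW * W - k_WP * P)
        dP = P * (rho_P - k_PP * P - k_PW * W)
        W = W + dt * dW
        P = P + dt * dP
        if np.any(W < 0) or np.any(P < 0):
            clamped += 1
            np.maximum(W, 0.0, out=W)
            np.maximum(P, 0.0, out=P)
    if clamped:
        log.debug("negative-population clamp applied on %d Euler steps", clamped)
    return out_W, out_P


def _euler_resource_batch(params, W0, P0, R0, dt, n_steps, sample_steps,
                          param_arrays=None):
    """Advance the resource model for a batch of wells."""
    if param_arrays is None:
        param_arrays = (
            params.alpha_W,
            params.alpha_P,
            params.delta_W,
            params.delta_P,
            params.gamma_W,
            params.gamma_P,
            params.r_W,
            params.r_P,
        )
    alpha_W, alpha_P, delta_W, delta_P, gamma_W, gamma_P, r_W, r_P = param_arrays

    W = np.asarray(W0, dtype=float)
    P = np.asarray(P0, dtype=float)
    R = np.asarray(R0, dtype=float)
    W, P, R = np.broadcast_arrays(W, P, R)
    W, P, R = W.copy(), P.copy(), R.copy()

    out_W = np.empty((len(sample_steps),) + W.shape)
    out_P = np.empty_like(out_W)
    out_R = np.empty_like(out_W)
    sample_set = {int(s): i for i, s in enumerate(sample_steps)}

    clamped = 0
    for step in range(n_steps + 1):
        if step in sample_set:
            i = sample_set[step]
            out_W[i] = W
            out_P[i] = P
            out_R[i] = R
        if step == n_steps:
            break
        starving_W = R < r_W
        starving_P = R < r_P
        dW = W * (alpha_W - delta_W * starving_W)
        dP = P * (alpha_P - delta_P * starving_P)
        dR = -(gamma_W * W + gamma_P * P) * (R > 0)
        W = W + dt * dW
        P = P + dt * dP
        R = R + dt * dR
        if np.any(W < 0) or np.any(P < 0) or np.any(R < 0):
            clamped += 1
            np.maximum(W, 0.0, out=W)
            np.maximum(P, 0.0, out=P)
            np.maximum(R, 0.0, out=R)
    if clamped:
        log.debug("negative clamp applied on %d Euler steps", clamped)
    return out_W, out_P, out_R
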