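"""Right-hand sides of the two competition ODE models.

Direct competition (Lotka-Volterra)::

    dW/dt = W * (rho_W - k_WW*W - k_WP*P)
    dP/dt = P * (rho_P - k_PP*P - k_PW*W)

Resource competition (Heaviside starvation switch)::

    dW/dt = W * (alpha_W - delta_W * [R < r_W])
    dP/dt = P * (alpha_P - delta_P * [R < r_P])
    dR/dt = -(gamma_W*W + gamma_P*P) * [R > 0]

The indicator brackets use strict inequalities: a resource level exactly at a
species' characteristic concentration still counts as available (no starvation
death), and a fully depleted resource is no longer consumed.
"""

from __future__ import annotations

import math
from typing import Tuple

from .params import DirectParams, PopulationState, ResourceParams

__all__ = ["direct_rhs", "resource_rhs"]


def _validate_state(state: PopulationState, need_resource: bool) -> None:
    # PopulationState validates on construction; guard against mutated floats
    for name in ("W", "P"):
        v = getattr(state, name)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"state.{name} must be finite and >= 0, got {v!r}")
    if need_resource:
        if state.R is None:
            raise ValueError("resource model requires state.R")
        if not math.isfinite(state.R) or state.R < 0:
            raise ValueError(f"state.R must be finite and >= 0, got {state.R!r}")


def direct_rhs(state: PopulationState, params: DirectParams) -> Tuple[float, float]:
    """Time derivatives (dW/dt, dP/dt) of the direct competition model.

    Per-capita growth of each species is its intrinsic rate reduced
    proportionally to every neighbour count, so crowded wells have negative
    net growth and an absent species stays extinct exactly.
    """
    _validate_state(state, need_resource=False)
    W, P = state.W, state.P
    dW = W * (params.rho_W - params.k_WW * W - params.k_WP * P)
    dP = P * (params.rho_P - params.k_PP * P - params.k_PW * W)
    return dW, dP


def resource_rhs(
    state: PopulationState, params: ResourceParams
) -> Tuple[float, float, float]:
    """Time derivatives (dW/dt, dP/dt, dR/dt) of the resource model.

    While the resource exceeds a species' characteristic concentration the
    species grows at its maximum net rate ``alpha_i``; once the resource
    falls strictly below, starvation apoptosis ``delta_i`` switches on.
    Depletion is proportional to the populations and stops at R = 0, so
    dR/dt <= 0 always and the resource can never recover.
    """
    _validate_state(state, need_resource=True)
    W, P, R = state.W, state.P, state.R
    starving_W = 1.0 if R < params.r_W else 0.0
    starving_P = 1.0 if R < params.r_P else 0.0
    dW = W * (params.alpha_W - params.delta_W * starving_W)
    dP = P * (params.alpha_P - params.delta_P * starving_P)
    dR = -(params.gamma_W * W + params.gamma_P * P) * (1.0 if R > 0 else 0.0)
    return dW, dP, dR
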