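"""Parameter containers for the competition models.

Two rival descriptions of wild-type (W) / p53-null (P) ESC co-culture dynamics
are supported:

* a *direct* Lotka-Volterra competition model with intrinsic net growth rates
  ``rho_i`` (per day) and four pairwise competition strengths ``k_{ij}``
  (per cell per day), indexed ``k_{affected, effector}``;
* a *resource* competition model in which a shared chemical resource R is
  depleted by both populations and starvation switches on an apoptotic rate.

All populations are raw cells per well (a plating of 0.4e5 is stored as
40000.0); time is in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Optional

__all__ = [
    "DirectParams",
    "ResourceParams",
    "PopulationState",
    "InterventionSchedule",
    "INTERVENTION_MODES",
    "params_at_time",
]


def _check_positive_finite(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DirectParams:
    """Rates of the direct Lotka-Volterra competition model.

    ``rho_W``, ``rho_P``
        Intrinsic (low-density) net growth rates, per day.
    ``k_WW``, ``k_WP``, ``k_PW``, ``k_PP``
        Competition strengths, per (cell . day).  First subscript is the
        affected species, second the effector: ``k_WP`` is the suppression
        that P cells exert on W cells.  The homotypic carrying capacity of
        species i alone is ``rho_i / k_ii``.
    """

    rho_W: float
    rho_P: float
    k_WW: float
    k_WP: float
    k_PW: float
    k_PP: float

    names = ("rho_W", "rho_P", "k_WW", "k_WP", "k_PW", "k_PP")

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive_finite(f.name, getattr(self, f.name))

    def to_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "DirectParams":
        return cls(**{n: float(v) for n, v in zip(cls.names, arr, strict=True)})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.names}

    @classmethod
    def from_dict(cls, d: dict) -> "DirectParams":
        return cls(**{n: float(d[n]) for n in cls.names})


@dataclass(frozen=True)
class ResourceParams:
    """Rates of the shared-resource competition model.

    ``alpha_W``, ``alpha_P``
        Maximum net proliferation rates, per day.
    ``delta_W``, ``delta_P``
        Intrinsic apoptotic rates under resource exhaustion, per day
        (``alpha_i - delta_i`` may be negative: starved populations decline).
    ``gamma_W``, ``gamma_P``
        Per-cell resource depletion rates, resource-units per (cell . day).
    ``r_W``, ``r_P``
        Characteristic resource concentrations below which species i starves.
    ``R0``
        Initial resource level.  Resource units are arbitrary and fixed by R0.
    """

    alpha_W: float
    alpha_P: float
    delta_W: float
    delta_P: float
    gamma_W: float
    gamma_P: float
    r_W: float
    r_P: float
    R0: float

    names = (
        "alpha_W",
        "alpha_P",
        "delta_W",
        "delta_P",
        "gamma_W",
        "gamma_P",
        "r_W",
        "r_P",
        "R0",
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive_finite(f.name, getattr(self, f.name))

    def to_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ResourceParams":
        return cls(**{n: float(v) for n, v in zip(cls.names, arr, strict=True)})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.names}

    @classmethod
    def from_dict(cls, d: dict) -> "ResourceParams":
        return cls(**{n: float(d[n]) for n in cls.names})


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous state of a well: cell counts, optional resource, time."""

    W: float
    P: float
    R: Optional[float] = None
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("W", "P"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.R is not None:
            if not math.isfinite(self.R):
                raise ValueError(f"R must be finite, got {self.R!r}")
            if self.R < 0:
                raise ValueError(f"R must be >= 0, got {self.R!r}")
        if not math.isfinite(self.t):
            raise ValueError(f"t must be finite, got {self.t!r}")


INTERVENTION_MODES = ("full", "growth_only", "competition_only")


@dataclass(frozen=True)
class InterventionSchedule:
    """Doxycycline-style intervention: an instantaneous parameter switch.

    From ``t_dox`` (days) onward the wild-type parameters are reset toward the
    p53-null ones, emulating BCL2 induction:

    * ``full`` -- remove both asymmetries (``rho_W <- rho_P`` and
      ``k_WP <- k_WW``);
    * ``growth_only`` -- remove only the intrinsic-growth asymmetry;
    * ``competition_only`` -- remove only the competition asymmetry.

    ``t_dox = None`` means the intervention never happens.
    """

    t_dox: Optional[float] = None
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in INTERVENTION_MODES:
            raise ValueError(
                f"mode must be one of {INTERVENTION_MODES}, got {self.mode!r}"
            )
        if self.t_dox is not None:
            if not math.isfinite(self.t_dox) or self.t_dox < 0:
                raise ValueError(f"t_dox must be >= 0, got {self.t_dox!r}")


def params_at_time(
    base: DirectParams,
    schedule: Optional[InterventionSchedule],
    t: float,
) -> DirectParams:
    """Effective direct-model parameters at time ``t`` under an intervention.

    Before ``t_dox`` (or with no schedule) the base parameters apply
    unchanged.  From ``t_dox`` onward the wild-type asymmetries are removed
    according to the schedule mode.  The mapping is idempotent: applying it
    to an already-switched parameter set changes nothing.
    """
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"t must be >= 0 and finite, got {t!r}")
    if schedule is None or schedule.t_dox is None or t < schedule.t_dox:
        return base
    if schedule.mode == "full":
        return replace(base, rho_W=base.rho_P, k_WP=base.k_WW)
    if schedule.mode == "growth_only":
        return replace(base, rho_W=base.rho_P)
    if schedule.mode == "competition_only":
        return replace(base, k_WP=base.k_WW)
    raise ValueError(f"unknown intervention mode {schedule.mode!r}")
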