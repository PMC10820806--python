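"""Prior specifications for Bayesian inference of the competition models.

Priors are independent uniforms on a stated scale per parameter — log10 by
default, which is the natural "equally compatible with different hypotheses"
choice for rates whose order of magnitude is unknown a priori.  The default
direct-model bounds bracket carrying capacities from 1e2 to 1e9 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .params import DirectParams, ResourceParams

__all__ = ["PriorSpec", "default_direct_prior", "default_resource_prior"]

_SCALES = ("linear", "log10")


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter uniform bounds on a stated scale.

    ``bounds`` maps parameter name -> (lower, upper) on the *natural* scale;
    ``scales`` maps name -> 'linear' or 'log10'.  Sampling and MCMC moves
    happen on the stated scale; draws are reported on the natural scale.
    """

    bounds: Dict[str, Tuple[float, float]]
    scales: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("prior must cover at least one parameter")
        for name, (lo, hi) in self.bounds.items():
            scale = self.scales.get(name)
            if scale not in _SCALES:
                raise ValueError(f"{name}: scale must be one of {_SCALES}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: need finite lower < upper, got {(lo, hi)}")
            if lo <= 0:
                raise ValueError(f"{name}: bounds must be strictly positive")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.bounds)

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def _scaled_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.dim)
        hi = np.empty(self.dim)
        for i, name in enumerate(self.names):
            a, b = self.bounds[name]
            if self.scales[name] == "log10":
                a, b = np.log10(a), np.log10(b)
            lo[i], hi[i] = a, b
        return lo, hi

    def to_sampled(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale parameter vector(s) -> sampling-scale coordinates."""
        theta = np.asarray(theta, dtype=float)
        z = theta.copy()
        for i, name in enumerate(self.names):
            if self.scales[name] == "log10":
                z[..., i] = np.log10(theta[..., i])
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        theta = z.copy()
        for i, name in enumerate(self.names):
            if self.scales[name] == "log10":
                theta[..., i] = 10.0 ** z[..., i]
        return theta

    def contains(self, theta: np.ndarray) -> np.ndarray:
        """Whether natural-scale vector(s) lie inside the support."""
        theta = np.asarray(theta, dtype=float)
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return np.all((theta >= lo) & (theta <= hi), axis=-1)

    def in_support_sampled(self, z: np.ndarray) -> np.ndarray:
        lo, hi = self._scaled_bounds()
        return np.all((z >= lo) & (z <= hi), axis=-1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` natural-scale vectors uniformly on the sampling scale."""
        lo, hi = self._scaled_bounds()
        z = rng.uniform(lo, hi, size=(n, self.dim))
        return self.to_natural(z)

    def collapse_to(self, theta: np.ndarray, eps: float = 1e-9) -> "PriorSpec":
        """Point-mass-like prior around ``theta`` (testing aid)."""
        bounds = {}
        for name, v in zip(self.names, np.asarray(theta, dtype=float)):
            bounds[name] = (float(v) * (1 - eps), float(v) * (1 + eps))
        return PriorSpec(bounds=bounds, scales=dict(self.scales))

    def to_dict(self) -> dict:
        return {
            name: {
                "lower": self.bounds[name][0],
                "upper": self.bounds[name][1],
                "scale": self.scales[name],
            }
            for name in self.names
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        bounds = {k: (float(v["lower"]), float(v["upper"])) for k, v in d.items()}
        scales = {k: str(v.get("scale", "log10")) for k, v in d.items()}
        return cls(bounds=bounds, scales=scales)


def default_direct_prior() -> PriorSpec:
    """Log-uniform prior for the six direct-competition rates.

    rho in [1e-2, 1e1] per day; k in [1e-8, 1e-2] per (cell . day).
    """
    bounds = {}
    for name in DirectParams.names:
        bounds[name] = (1e-2, 1e1) if name.startswith("rho") else (1e-8, 1e-2)
    return PriorSpec(bounds=bounds, scales={n: "log10" for n in bounds})


def default_resource_prior() -> PriorSpec:
    """Log-uniform prior for the identifiable resource-model rates.

    alpha, delta in [1e-2, 1e1] per day; gamma in [1e-9, 1e-3] resource-units
    per (cell . day); r in [1e-3, 1e3] resource-units.  The resource unit is
    unobservable — the dynamics are invariant under jointly rescaling
    (gamma, r, R0) — so the unit is pinned by fixing R0 = 1 during fitting
    (see ``sample_posterior``) and R0 is not part of the default prior.
    Supplying a custom prior that covers R0 re-enables sampling it.
    """
    bounds = {}
    for name in ResourceParams.names:
        if name == "R0":
            continue
        if name.startswith(("alpha", "delta")):
            bounds[name] = (1e-2, 1e1)
        elif name.startswith("gamma"):
            bounds[name] = (1e-9, 1e-3)
        else:  # r_W, r_P
            bounds[name] = (1e-3, 1e3)
    return PriorSpec(bounds=bounds, scales={n: "log10" for n in bounds})
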