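"""Synthetic growth-curve generation.

Raw counts from these competition assays are not bundled with the package;
analyses are driven by synthetic datasets with the assumed statistical
structure: deterministic model
trajectories (direct or resource competition) observed daily over four days
in ~3 replicate wells, with Gaussian counting noise whose standard deviation
is the square root of the population size.  Counts are rounded to whole
cells and floored at zero; day-0 records report the plated numbers exactly.

``default_conditions`` provides the reference plating designs: the core
separate/co-culture triplet, a 24-condition density-by-ratio grid (this
package's stand-in for an unenumerated extended design), the
wild-type:mutant ratio series, and the doxycycline-rescue series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np

from .data import Condition, GrowthDataset
from .params import DirectParams, InterventionSchedule, PopulationState, ResourceParams
from .solver import DEFAULT_DT, integrate

__all__ = [
    "GeneratorSpec",
    "default_conditions",
    "generate",
    "recovery_truth",
    "resource_demo_truth",
    "CONDITION_STYLES",
]

CONDITION_STYLES = ("paper_core", "grid24", "rescue", "ratios")

DAYS = (0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic experiment.

    ``truth`` fixes the generating model (DirectParams -> direct model,
    ResourceParams -> resource model); ``noise`` is ``'gaussian_sqrtN'``
    (counting noise, the default) or ``'none'`` (noise-free trajectories,
    useful for oracle tests).
    """

    truth: Union[DirectParams, ResourceParams]
    conditions: Sequence[Condition]
    replicates: int = 3
    noise: str = "gaussian_sqrtN"
    seed: int = 0
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.noise not in ("gaussian_sqrtN", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def model(self) -> str:
        return "direct" if isinstance(self.truth, DirectParams) else "resource"


def recovery_truth() -> DirectParams:
    """Canonical ground truth for parameter-recovery experiments.

    Wild type grows at 0.9/day, the p53-null mutant at 1.1/day; three of the
    four competition strengths are equal (homotypic carrying capacity 2e5
    cells) while the mutant suppresses the wild type three times as strongly
    (k_WP = 3 k_WW) — the asymmetric super-competition signature.
    """
    k = 0.9 / 2e5
    return DirectParams(rho_W=0.9, rho_P=1.1, k_WW=k, k_WP=3 * k, k_PW=k, k_PP=k)


def resource_demo_truth() -> ResourceParams:
    """Reference truth for resource-model experiments.

    Chosen so that with the core platings the resource runs out within the
    4-day window: populations grow exponentially at alpha_i, then the
    wild type (higher characteristic concentration r_W) starves first and
    declines at alpha_i - delta_i — the kinked growth-then-collapse shape
    characteristic of nutrient competition.
    """
    return ResourceParams(
        alpha_W=0.9,
        alpha_P=1.1,
        delta_W=2.0,
        delta_P=2.0,
        gamma_W=5e-7,
        gamma_P=5e-7,
        r_W=0.3,
        r_P=0.05,
        R0=1.0,
    )


def _mix(total: float, w_parts: float, p_parts: float, cid: str) -> Condition:
    frac_w = w_parts / (w_parts + p_parts)
    return Condition(
        id=cid,
        W0=round(total * frac_w),
        P0=round(total * (1.0 - frac_w)),
        sample_days=DAYS,
    )


def default_conditions(style: str) -> List[Condition]:
    """Named plating designs.

    ``paper_core``
        Separate cultures of 0.8e5 cells of each genotype plus a 0.4+0.4e5
        co-culture, counted daily over 4 days.
    ``grid24``
        24 conditions crossing total densities {0.16, 0.8, 2, 10}e5 with
        W:P mixes {1:0, 0:1, 1:1, 2:1, 1:3, 1:10} — this package's
        stand-in for an unenumerated extended plating design.
    ``ratios``
        Co-cultures at wild-type:mutant ratios 1:1, 1:3, 1:5, 1:10
        (W0 fixed at 0.4e5).
    ``rescue``
        The 0.4+0.4e5 co-culture untreated and with full doxycycline rescue
        starting at days 0, 2 and 3.
    """
    if style == "paper_core":
        return [
            Condition(id="W_alone", W0=8e4, P0=0.0, sample_days=DAYS),
            Condition(id="P_alone", W0=0.0, P0=8e4, sample_days=DAYS),
            Condition(id="co_1to1", W0=4e4, P0=4e4, sample_days=DAYS),
        ]
    if style == "grid24":
        conditions = []
        totals = (0.16e5, 0.8e5, 2e5, 10e5)
        mixes = (("1to0", 1, 0), ("0to1", 0, 1), ("1to1", 1, 1),
                 ("2to1", 2, 1), ("1to3", 1, 3), ("1to10", 1, 10))
        for total in totals:
            for tag, w, p in mixes:
                cid = f"grid_t{total / 1e5:g}_{tag}"
                conditions.append(_mix(total, w, p, cid))
        return conditions
    if style == "ratios":
        return [
            Condition(
                id=f"ratio_1to{r}", W0=0.4e5, P0=0.4e5 * r, sample_days=DAYS
            )
            for r in (1, 3, 5, 10)
        ]
    if style == "rescue":
        conds = [
            Condition(id="rescue_untreated", W0=4e4, P0=4e4, sample_days=DAYS)
        ]
        for day in (0.0, 2.0, 3.0):
            conds.append(
                Condition(
                    id=f"rescue_dox{day:g}",
                    W0=4e4,
                    P0=4e4,
                    sample_days=DAYS,
                    schedule=InterventionSchedule(t_dox=day, mode="full"),
                )
            )
        return conds
    raise ValueError(f"unknown condition style {style!r}; have {CONDITION_STYLES}")


def generate(spec: GeneratorSpec) -> GrowthDataset:
    """Simulate a growth dataset from a generator specification.

    For every condition x replicate x sample day x plated species the count
    is ``max(0, round(x_model + e))`` with ``e ~ N(0, sqrt(max(x_model, 1)))``
    under sqrt-N noise, the exact model value under ``noise='none'``, and the
    plated number exactly at day 0.  Species that were not plated in a
    condition are not recorded (they are not measured in the assay).
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    records = []
    for cond in spec.conditions:
        initial = PopulationState(
            W=cond.W0,
            P=cond.P0,
            R=spec.truth.R0 if model == "resource" else None,
        )
        traj = integrate(
            model,
            spec.truth,
            initial,
            t_end=cond.t_end,
            dt=spec.dt,
            sample_times=cond.sample_days,
            schedule=cond.schedule,
        )
        observed = []
        if cond.W0 > 0:
            observed.append(("W", cond.W0, traj.W))
        if cond.P0 > 0:
            observed.append(("P", cond.P0, traj.P))
        for rep in range(1, spec.replicates + 1):
            rep_id = f"r{rep}"
            for day_i, day in enumerate(cond.sample_days):
                for species, plated, series in observed:
                    x = float(series[day_i])
                    if day == 0.0:
                        count = float(plated)
                    elif spec.noise == "none":
                        count = x
                    else:
                        e = rng.normal(0.0, math.sqrt(max(x, 1.0)))
                        count = max(0.0, round(x + e))
                    records.append((cond.id, rep_id, day, species, count))
    return GrowthDataset.from_records(records)
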