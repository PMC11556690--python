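"""Discounted cohort run per arm and incremental cost-effectiveness outcomes.

The cohort model is an expectation over annual cycles: each cycle contributes
survival(t) * discount(t) * (occupancy-weighted utility or cost), with
discount(t) = (1+r)^-(t-1) so cycle 1 is undiscounted, no half-cycle
correction, and the one-time intervention cost added undiscounted at model
start.  The headline outcome is the ICER,

    ICER = (Cost_MDMA-AT - Cost_PT) / (QALY_MDMA-AT - QALY_PT),

reported only in the NE/SW quadrants of the cost-effectiveness plane;
dominance is flagged otherwise.  Net monetary benefit at willingness-to-pay
lambda is NMB = lambda * dQALY - dCost.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cost_engine import (
    CostBreakdown,
    cycle_treatment_cost,
    cycle_visit_cost,
    intervention_cost,
)
from .model_inputs import Arm, ModelConfig, StateDistribution, UtilityValues
from .trajectory import build_schedule

__all__ = [
    "ArmResult",
    "CeaResult",
    "discount_factor",
    "cycle_utility",
    "run_arm",
    "compare",
    "run_cea",
]


def discount_factor(cycle: int, rate: float) -> float:
    """(1+rate)^-(cycle-1); the first cycle is undiscounted by convention."""
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    return (1.0 + rate) ** -(cycle - 1)


def cycle_utility(distribution: StateDistribution, utilities: UtilityValues) -> float:
    """Occupancy-weighted EQ-5D-5L utility for one cycle."""
    return float(distribution.as_array() @ utilities.as_array())


@dataclass(frozen=True)
class ArmResult:
    """Discounted costs and QALYs for one arm, with the per-cycle trace."""

    arm: Arm
    costs: CostBreakdown
    qalys: float
    trace: pd.DataFrame

    @property
    def total_cost(self) -> float:
        return self.costs.total


@dataclass(frozen=True)
class CeaResult:
    """Incremental outcomes of the reference arm versus the comparator."""

    incremental_cost: float
    incremental_qaly: float
    icer: Optional[float]
    dominance: Optional[str]  # 'dominant' | 'dominated' | 'undefined' | None
    quadrant: str  # NE | NW | SE | SW
    nmb: float
    wtp: float


def run_arm(config: ModelConfig, arm: Arm) -> ArmResult:
    """Run the discounted cohort model for one arm over the configured horizon."""
    sched = config.schedule
    schedule = build_schedule(config, arm)
    inputs = config.arm(arm)
    horizon = sched.horizon_years

    rows = []
    qalys = 0.0
    visits = np.zeros(horizon)
    treatment = np.zeros(horizon)
    for t in range(1, horizon + 1):
        dist = schedule.distributions[t - 1]
        utils = inputs.cycle1_utilities if t == 1 else inputs.later_utilities
        active = 12 - sched.treatment_period_months if t == 1 else 12
        w = schedule.survival[t - 1] * discount_factor(t, sched.discount_rate)
        u = cycle_utility(dist, utils)
        v = cycle_visit_cost(dist, config.costs.monthly_visit_cost, 12)
        c = cycle_treatment_cost(dist, config.costs.monthly_treatment_cost, active)
        qalys += w * u
        visits[t - 1] = w * v
        treatment[t - 1] = w * c
        rows.append(
            {
                "cycle": t,
                "no_ptsd": dist.no_ptsd,
                "non_severe": dist.non_severe,
                "severe": dist.severe,
                "survival": schedule.survival[t - 1],
                "discount": discount_factor(t, sched.discount_rate),
                "utility": u,
                "discounted_qaly": w * u,
                "discounted_visit_cost": w * v,
                "discounted_treatment_cost": w * c,
            }
        )

    breakdown = CostBreakdown(
        intervention=intervention_cost(config, arm),
        visits=float(visits.sum()),
        treatment=float(treatment.sum()),
        visits_by_cycle=visits,
        treatment_by_cycle=treatment,
    )
    return ArmResult(arm=arm, costs=breakdown, qalys=qalys, trace=pd.DataFrame(rows))


def compare(ref: ArmResult, comp: ArmResult, wtp: float) -> CeaResult:
    """Incremental outcomes ref-minus-comp; the ICER only where it is meaningful."""
    d_cost = ref.total_cost - comp.total_cost
    d_qaly = ref.qalys - comp.qalys
    nmb = wtp * d_qaly - d_cost

    if d_qaly > 0:
        quadrant = "NE" if d_cost >= 0 else "SE"
    elif d_qaly < 0:
        quadrant = "NW" if d_cost >= 0 else "SW"
    else:
        quadrant = "NE" if d_cost >= 0 else "SE"

    icer: Optional[float] = None
    dominance: Optional[str] = None
    if d_qaly == 0.0:
        dominance = None if d_cost == 0.0 else "undefined"
    elif quadrant == "SE":
        dominance = "dominant"  # more effect, lower cost
    elif quadrant == "NW":
        dominance = "dominated"
    else:
        icer = d_cost / d_qaly

    return CeaResult(
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        dominance=dominance,
        quadrant=quadrant,
        nmb=nmb,
        wtp=wtp,
    )


def run_cea(config: ModelConfig) -> tuple[ArmResult, ArmResult, CeaResult]:
    """Run both arms under one config and compare (MDMA-AT as reference)."""
    ref = run_arm(config, Arm.MDMA_AT)
    comp = run_arm(config, Arm.PT)
    return ref, comp, compare(ref, comp, config.schedule.wtp)
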