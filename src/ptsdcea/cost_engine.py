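"""Cost build-up: session arithmetic, one-time intervention costs, cycle costs.

Three direct-cost components per arm, payer perspective:

* intervention — one-time course cost at model start (3 preparation sessions,
  3 interventional sessions with the drug price included in the MDMA-AT arm
  only, 9 integration sessions; all sessions staffed by two therapists);
* PTSD healthcare visits — monthly per-state visit cost, occupancy-weighted,
  accrued all 12 months of every cycle;
* regular PTSD treatment — monthly per-state psychotherapy/medication cost,
  occupancy-weighted, excluded while the treatment course is running (the
  first ``treatment_period_months`` of cycle 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_inputs import Arm, ModelConfig, StateDistribution, StateValues

__all__ = [
    "CostBreakdown",
    "session_cost",
    "intervention_cost",
    "per_interventional_session_price",
    "cycle_visit_cost",
    "cycle_treatment_cost",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted cost components for one arm, with the per-cycle trace."""

    intervention: float
    visits: float
    treatment: float
    visits_by_cycle: np.ndarray = field(default_factory=lambda: np.zeros(0))
    treatment_by_cycle: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def total(self) -> float:
        return self.intervention + self.visits + self.treatment


def session_cost(
    base_90min_single_therapist_cost: float,
    duration_minutes: float,
    n_therapists: int,
) -> float:
    """Session price scaled from a single-therapist 90-minute base rate.

    cost = base * (duration / 90) * n_therapists; e.g. a $221 base rate gives
    $442 for a two-therapist 90-minute session and ~$2,357 for 8 hours.
    """
    if base_90min_single_therapist_cost <= 0:
        raise ValueError("base session cost must be > 0")
    if duration_minutes <= 0:
        raise ValueError("duration_minutes must be > 0")
    if n_therapists <= 0:
        raise ValueError("n_therapists must be > 0")
    return base_90min_single_therapist_cost * (duration_minutes / 90.0) * n_therapists


def intervention_cost(config: ModelConfig, arm: Arm) -> float:
    """One-time treatment-course cost, charged undiscounted at model start.

    The comparator runs the identical psychotherapy protocol with the drug
    price set to zero.
    """
    sched = config.schedule
    costs = config.costs
    drug = costs.mdma_price_per_session if arm is Arm.MDMA_AT else 0.0
    return (
        sched.n_prep_sessions * costs.prep_session_cost
        + sched.n_interventional_sessions
        * (drug + costs.interventional_psychotherapy_cost)
        + sched.n_integration_sessions * costs.integration_session_cost
    )


def per_interventional_session_price(config: ModelConfig) -> float:
    """Full course cost expressed per interventional session (MDMA-AT arm)."""
    n = config.schedule.n_interventional_sessions
    if n == 0:
        raise ValueError("n_interventional_sessions must be > 0")
    return intervention_cost(config, Arm.MDMA_AT) / n


def cycle_visit_cost(
    distribution: StateDistribution,
    monthly_visit_cost: StateValues,
    months: float = 12.0,
) -> float:
    """Undiscounted occupancy-weighted PTSD visit cost over ``months``."""
    if months < 0:
        raise ValueError("months must be >= 0")
    return months * float(distribution.as_array() @ monthly_visit_cost.as_array())


def cycle_treatment_cost(
    distribution: StateDistribution,
    monthly_treatment_cost: StateValues,
    active_months: float,
) -> float:
    """Undiscounted occupancy-weighted regular PTSD treatment cost.

    The caller passes ``12 - treatment_period_months`` for cycle 1 (treatment
    costs are excluded while intervention sessions run) and 12 afterwards.
    """
    if not 0 <= active_months <= 12:
        raise ValueError("active_months must be in [0, 12]")
    return active_months * float(
        distribution.as_array() @ monthly_treatment_cost.as_array()
    )
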