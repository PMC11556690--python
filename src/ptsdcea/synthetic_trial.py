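"""Synthetic patient-level trial data with the structure the model assumes.

The real patient-level data behind the analysis (two phase-III trials plus a
long-term follow-up) are not publicly available, so this module generates
cohorts with the same statistical skeleton: per-patient CAPS-5 severity
scores at enrollment, the 4-month post-treatment endpoint, and ~17-month
follow-up; adjudicated loss-of-diagnosis flags; EQ-5D-5L utilities; and
withdrawal/death events.  It also implements the state-classification rules
used to turn those measurements into model health states:

* death -> DEATH; withdrawal -> Severe PTSD;
* loss of PTSD diagnosis (criteria no longer met) -> No PTSD;
* baseline-severe patients: treatment response (CAPS-5 decrease >= 10
  points) -> Non-severe PTSD, otherwise Severe PTSD;
* baseline-moderate patients who still meet criteria -> Non-severe PTSD
  regardless of response.

Generator defaults are calibrated so that the expected 4-month and 17-month
occupancies, pushed through the log-model extrapolation, land on the
published cycle-1 and cycles-2+ distributions; per-state EQ-5D-5L means
default to the published per-arm values.  That makes the full input-derivation
pathway (cohort -> timepoint distributions -> extrapolation -> model config ->
ICER) testable end to end.
"""
from __future__ import annotations

import enum
import pathlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model_inputs import (
    ALIVE_STATES,
    Arm,
    ArmInputs,
    HealthState,
    ModelConfig,
    StateDistribution,
    UtilityValues,
    builtin_base_case,
)
from .trajectory import TimedDistribution, estimate_cycle1_distribution

__all__ = [
    "Timepoint",
    "TIMEPOINT_MONTHS",
    "SyntheticPatient",
    "GeneratorSpec",
    "DerivedInputs",
    "generate_cohort",
    "classify_state",
    "derive_model_inputs",
    "config_from_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

CAPS5_MAX = 80.0
RESPONSE_THRESHOLD = 10.0  # clinically relevant CAPS-5 decrease


class Timepoint(str, enum.Enum):
    ENROLLMENT = "enrollment"
    POST_TREATMENT = "post_treatment"  # end of the 4-month treatment course
    FOLLOW_UP = "follow_up"  # ~17-month long-term follow-up


TIMEPOINT_MONTHS = {
    Timepoint.ENROLLMENT: 0.0,
    Timepoint.POST_TREATMENT: 4.0,
    Timepoint.FOLLOW_UP: 17.0,
}


class MissingTimepointError(ValueError):
    """The patient has no measurement at the requested timepoint."""


@dataclass(frozen=True)
class SyntheticPatient:
    id: str
    arm: Arm
    baseline_class: str  # 'moderate' | 'severe'
    caps5: dict[Timepoint, float]
    meets_criteria: dict[Timepoint, bool]
    eq5d5l: dict[Timepoint, float]
    withdrew: bool
    died: bool


def _table1_utilities() -> dict[str, dict[str, dict[str, float]]]:
    base = builtin_base_case()
    out: dict[str, dict[str, dict[str, float]]] = {"post_treatment": {}, "follow_up": {}}
    for arm in Arm:
        out["post_treatment"][arm.value] = dict(
            base.arms[arm].cycle1_utilities.model_dump()
        )
        out["follow_up"][arm.value] = dict(base.arms[arm].later_utilities.model_dump())
    return out


class GeneratorSpec(BaseModel):
    """Data-generating parameters for one synthetic trial cohort.

    Defaults emulate the pooled phase-III population: ~200 participants per
    arm, mean baseline CAPS-5 around 35 (moderate) / 50 (severe), a mean
    4-month CAPS-5 change of -24 (MDMA-AT) vs -14 (PT) points, and
    loss-of-diagnosis probabilities chosen so the expected classified
    occupancies reproduce the published cycle-1 / cycles-2+ distributions.
    """

    model_config = ConfigDict(frozen=True)

    n_per_arm: int = Field(default=200, ge=0)
    seed: Optional[int] = None
    p_moderate: float = Field(default=0.30, ge=0.0, le=1.0)
    baseline_mean: dict[str, float] = {"moderate": 35.0, "severe": 50.0}
    baseline_sd: dict[str, float] = {"moderate": 6.0, "severe": 8.0}
    effect_mean: dict[Arm, float] = {Arm.MDMA_AT: -18.5, Arm.PT: -8.8}
    effect_sd: dict[Arm, float] = {Arm.MDMA_AT: 12.0, Arm.PT: 12.0}
    followup_extra_mean: dict[Arm, float] = {Arm.MDMA_AT: -6.0, Arm.PT: 3.0}
    followup_extra_sd: float = 6.0
    p_loss_given_response: dict[Arm, float] = {Arm.MDMA_AT: 0.84, Arm.PT: 0.757}
    p_loss_retention: float = Field(default=0.97, ge=0.0, le=1.0)
    p_new_loss_followup: dict[Arm, float] = {Arm.MDMA_AT: 0.70, Arm.PT: 0.215}
    withdrawal_prob: dict[Arm, float] = {Arm.MDMA_AT: 0.05, Arm.PT: 0.05}
    death_prob: float = Field(default=0.002, ge=0.0, le=1.0)
    utility_mean_enrollment: dict[str, float] = {
        "no_ptsd": 0.80,
        "non_severe": 0.71,
        "severe": 0.60,
    }
    # per (timepoint, arm, state) EQ-5D-5L means; defaults are the published values
    utility_mean: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=_table1_utilities
    )
    utility_sd: float = Field(default=0.08, ge=0.0)

    @model_validator(mode="after")
    def _probabilities_valid(self) -> "GeneratorSpec":
        for name in ("p_loss_given_response", "p_new_loss_followup", "withdrawal_prob"):
            for arm, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{arm}] must be in [0, 1]")
        for cls, sd in self.baseline_sd.items():
            if sd < 0:
                raise ValueError(f"baseline_sd[{cls}] must be >= 0")
        return self


def generate_cohort(spec: GeneratorSpec) -> list[SyntheticPatient]:
    """Draw one reproducible synthetic cohort (both arms) from ``spec``."""
    if spec.seed is None:
        raise ValueError("GeneratorSpec.seed must be set for reproducible cohorts")
    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    for arm in Arm:
        n = spec.n_per_arm
        if n == 0:
            continue
        moderate = rng.random(n) < spec.p_moderate
        baseline = np.where(
            moderate,
            rng.normal(spec.baseline_mean["moderate"], spec.baseline_sd["moderate"], n),
            rng.normal(spec.baseline_mean["severe"], spec.baseline_sd["severe"], n),
        )
        baseline = np.clip(baseline, 0.0, CAPS5_MAX)
        withdrew = rng.random(n) < spec.withdrawal_prob[arm]
        died = rng.random(n) < spec.death_prob

        change4 = rng.normal(spec.effect_mean[arm], spec.effect_sd[arm], n)
        change4 = np.where(withdrew, 0.0, change4)
        caps4 = np.clip(baseline + change4, 0.0, CAPS5_MAX)
        responded4 = (baseline - caps4 >= RESPONSE_THRESHOLD) & ~withdrew
        lost4 = responded4 & (rng.random(n) < spec.p_loss_given_response[arm])

        extra = rng.normal(spec.followup_extra_mean[arm], spec.followup_extra_sd, n)
        extra = np.where(withdrew, 0.0, extra)
        capsfu = np.clip(caps4 + extra, 0.0, CAPS5_MAX)
        lostfu = np.where(
            lost4,
            rng.random(n) < spec.p_loss_retention,
            rng.random(n) < spec.p_new_loss_followup[arm],
        ) & ~withdrew

        util_noise = rng.normal(0.0, 1.0, (n, 3))

        for i in range(n):
            pid = f"{arm.value}-{i:05d}"
            caps = {
                Timepoint.ENROLLMENT: float(baseline[i]),
                Timepoint.POST_TREATMENT: float(caps4[i]),
                Timepoint.FOLLOW_UP: float(capsfu[i]),
            }
            meets = {
                Timepoint.ENROLLMENT: True,
                Timepoint.POST_TREATMENT: not bool(lost4[i]),
                Timepoint.FOLLOW_UP: not bool(lostfu[i]),
            }
            patient = SyntheticPatient(
                id=pid,
                arm=arm,
                baseline_class="moderate" if moderate[i] else "severe",
                caps5=caps,
                meets_criteria=meets,
                eq5d5l={},
                withdrew=bool(withdrew[i]),
                died=bool(died[i]),
            )
            utilities: dict[Timepoint, float] = {}
            for j, tp in enumerate(Timepoint):
                state = classify_state(patient, tp)
                if state is HealthState.DEATH:
                    utilities[tp] = float("nan")
                    continue
                if tp is Timepoint.ENROLLMENT:
                    mean = spec.utility_mean_enrollment[state.value]
                else:
                    mean = spec.utility_mean[tp.value][arm.value][state.value]
                utilities[tp] = float(
                    np.clip(mean + spec.utility_sd * util_noise[i, j], -1.0, 1.0)
                )
            patients.append(
                SyntheticPatient(
                    id=patient.id,
                    arm=patient.arm,
                    baseline_class=patient.baseline_class,
                    caps5=caps,
                    meets_criteria=meets,
                    eq5d5l=utilities,
                    withdrew=patient.withdrew,
                    died=patient.died,
                )
            )
    return patients


def classify_state(patient: SyntheticPatient, timepoint: Timepoint) -> HealthState:
    """Map one patient-timepoint to a model health state (total, deterministic).

    Death and withdrawal are post-treatment events: at enrollment every
    patient is classified by baseline severity (all meet PTSD criteria).
    """
    if timepoint not in patient.caps5:
        raise MissingTimepointError(
            f"patient {patient.id} has no measurement at {timepoint.value}"
        )
    if timepoint is Timepoint.ENROLLMENT:
        return (
            HealthState.NON_SEVERE_PTSD
            if patient.baseline_class == "moderate"
            else HealthState.SEVERE_PTSD
        )
    if patient.died:
        return HealthState.DEATH
    if patient.withdrew:
        return HealthState.SEVERE_PTSD
    if not patient.meets_criteria[timepoint]:
        return HealthState.NO_PTSD
    if patient.baseline_class == "severe":
        decrease = patient.caps5[Timepoint.ENROLLMENT] - patient.caps5[timepoint]
        return (
            HealthState.NON_SEVERE_PTSD
            if decrease >= RESPONSE_THRESHOLD
            else HealthState.SEVERE_PTSD
        )
    return HealthState.NON_SEVERE_PTSD


@dataclass(frozen=True)
class DerivedInputs:
    """Aggregates a cohort into model-ready occupancy series and utilities."""

    series: dict[Arm, list[TimedDistribution]]
    utilities: dict[Arm, dict[Timepoint, dict[HealthState, Optional[float]]]]


def derive_model_inputs(cohort: list[SyntheticPatient]) -> DerivedInputs:
    """Classified-state occupancy among alive patients and within-state mean utilities.

    A state with no members at a timepoint gets a ``None`` utility; the caller
    must supply a fallback.
    """
    series: dict[Arm, list[TimedDistribution]] = {}
    utilities: dict[Arm, dict[Timepoint, dict[HealthState, Optional[float]]]] = {}
    for arm in Arm:
        arm_patients = [p for p in cohort if p.arm is arm]
        if not arm_patients:
            raise ValueError(f"cohort has no patients in arm {arm.value}")
        series[arm] = []
        utilities[arm] = {}
        for tp in Timepoint:
            states = {p.id: classify_state(p, tp) for p in arm_patients}
            alive = [p for p in arm_patients if states[p.id] is not HealthState.DEATH]
            if not alive:
                raise ValueError(f"no alive patients in arm {arm.value} at {tp.value}")
            counts = {s: 0 for s in ALIVE_STATES}
            sums = {s: 0.0 for s in ALIVE_STATES}
            for p in alive:
                s = states[p.id]
                counts[s] += 1
                sums[s] += p.eq5d5l[tp]
            n_alive = len(alive)
            series[arm].append(
                TimedDistribution(
                    time_months=TIMEPOINT_MONTHS[tp],
                    distribution=StateDistribution(
                        no_ptsd=counts[HealthState.NO_PTSD] / n_alive,
                        non_severe=counts[HealthState.NON_SEVERE_PTSD] / n_alive,
                        severe=counts[HealthState.SEVERE_PTSD] / n_alive,
                    ),
                )
            )
            utilities[arm][tp] = {
                s: (sums[s] / counts[s] if counts[s] > 0 else None)
                for s in ALIVE_STATES
            }
    return DerivedInputs(series=series, utilities=utilities)


def config_from_cohort(
    cohort: list[SyntheticPatient],
    template: Optional[ModelConfig] = None,
    target_time: float = 12.0,
) -> tuple[ModelConfig, list[str]]:
    """Build a full model config from a synthetic cohort.

    Cycle-1 occupancy comes from the log-model extrapolation of the cohort's
    timepoint series; cycles-2+ occupancy from the follow-up timepoint.
    Cycle-1 utilities are the post-treatment within-state means, cycles-2+ the
    follow-up means.  Costs, schedule and mortality come from ``template``
    (the built-in base case by default), as do utilities for states with no
    members (returned as warnings).
    """
    template = template or builtin_base_case()
    derived = derive_model_inputs(cohort)
    warnings: list[str] = []
    arms: dict[Arm, ArmInputs] = {}
    for arm in Arm:
        cycle1 = estimate_cycle1_distribution(derived.series[arm], target_time)
        later = derived.series[arm][-1].distribution
        utils = {}
        for block, tp in (
            ("cycle1_utilities", Timepoint.POST_TREATMENT),
            ("later_utilities", Timepoint.FOLLOW_UP),
        ):
            values = {}
            for s in ALIVE_STATES:
                u = derived.utilities[arm][tp][s]
                if u is None:
                    u = getattr(template.arms[arm], block)[s]
                    warnings.append(
                        f"{arm.value}/{tp.value}/{s.value}: no patients; "
                        "utility taken from template"
                    )
                values[s.value] = u
            utils[block] = UtilityValues(**values)
        arms[arm] = ArmInputs(
            cycle1_distribution=cycle1,
            later_distribution=later,
            cycle1_utilities=utils["cycle1_utilities"],
            later_utilities=utils["later_utilities"],
        )
    config = ModelConfig(
        arms=arms,
        costs=template.costs,
        schedule=template.schedule,
        mortality=template.mortality,
        baseline_age=template.baseline_age,
    )
    return config, warnings


def cohort_to_frame(cohort: list[SyntheticPatient]) -> pd.DataFrame:
    """One row per patient-timepoint."""
    rows = []
    for p in cohort:
        for tp in Timepoint:
            rows.append(
                {
                    "id": p.id,
                    "arm": p.arm.value,
                    "baseline_class": p.baseline_class,
                    "timepoint": tp.value,
                    "time_months": TIMEPOINT_MONTHS[tp],
                    "caps5": p.caps5[tp],
                    "meets_criteria": p.meets_criteria[tp],
                    "eq5d5l": p.eq5d5l[tp],
                    "withdrew": p.withdrew,
                    "died": p.died,
                }
            )
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: list[SyntheticPatient], path: str | pathlib.Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | pathlib.Path) -> list[SyntheticPatient]:
    df = pd.read_csv(path)
    patients = []
    for (pid, arm_label), group in df.groupby(["id", "arm"], sort=True):
        by_tp = {Timepoint(row.timepoint): row for row in group.itertuples()}
        first = next(iter(by_tp.values()))
        patients.append(
            SyntheticPatient(
                id=str(pid),
                arm=Arm(arm_label),
                baseline_class=first.baseline_class,
                caps5={tp: float(r.caps5) for tp, r in by_tp.items()},
                meets_criteria={tp: bool(r.meets_criteria) for tp, r in by_tp.items()},
                eq5d5l={tp: float(r.eq5d5l) for tp, r in by_tp.items()},
                withdrew=bool(first.withdrew),
                died=bool(first.died),
            )
        )
    return patients
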