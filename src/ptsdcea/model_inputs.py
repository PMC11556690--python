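"""Model parameters: types, validation, the built-in base case, and config I/O.

Every number the cohort model consumes lives in a :class:`ModelConfig`. The
built-in base case carries the published inputs for the MDMA-assisted therapy
(MDMA-AT) versus placebo-with-therapy (PT) comparison in chronic PTSD of
moderate or higher severity: per-arm health-state occupancy for the first
annual cycle and for cycles 2+, per-session intervention costs, monthly
PTSD visit and treatment costs per state, EQ-5D-5L utilities per
(arm, state, cycle block), a 5-year cumulative mortality rate, and the
schedule/discount/willingness-to-pay settings.

Configs serialize to YAML (primary) or JSON; unspecified fields fall back to
the base-case defaults so a user file only needs the values it changes.
"""
from __future__ import annotations

import enum
import json
import pathlib
from typing import Any, Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "Arm",
    "CycleBlock",
    "StateDistribution",
    "StateValues",
    "UtilityValues",
    "CostParameters",
    "ArmInputs",
    "ScheduleParameters",
    "MortalityParameters",
    "ModelConfig",
    "ConfigError",
    "ConfigFormatError",
    "ConfigValidationError",
    "builtin_base_case",
    "load_config",
    "save_config",
    "validate_config",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFormatError(ConfigError):
    """The file could not be parsed as YAML/JSON."""


class ConfigValidationError(ConfigError):
    """Parsed fine but violates a model invariant; message names the field."""


class HealthState(str, enum.Enum):
    """The four model health states. DEATH is absorbing and carries no inputs."""

    NO_PTSD = "no_ptsd"
    NON_SEVERE_PTSD = "non_severe"
    SEVERE_PTSD = "severe"
    DEATH = "death"

    @property
    def alive(self) -> bool:
        return self is not HealthState.DEATH


#: The three alive states, in canonical (best-to-worst) order.
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.NO_PTSD,
    HealthState.NON_SEVERE_PTSD,
    HealthState.SEVERE_PTSD,
)


class Arm(str, enum.Enum):
    MDMA_AT = "mdma_at"
    PT = "pt"


class CycleBlock(str, enum.Enum):
    """Annual-cycle blocks with distinct occupancy/utility inputs."""

    CYCLE_1 = "cycle_1"
    CYCLES_2_PLUS = "cycles_2_plus"


# Published occupancy tables are printed to 2 decimals and sum to ~99.8%, not
# exactly 100%; sums within this slack are accepted and renormalized when the
# engine consumes them.  Stored values keep their printed precision.
_SUM_SLACK = 0.01


class StateDistribution(BaseModel):
    """Occupancy fractions over the three alive states for one cycle block."""

    model_config = ConfigDict(frozen=True)

    no_ptsd: float = Field(ge=0.0, le=1.0)
    non_severe: float = Field(ge=0.0, le=1.0)
    severe: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sum_close_to_one(self) -> "StateDistribution":
        s = self.no_ptsd + self.non_severe + self.severe
        if abs(s - 1.0) > _SUM_SLACK:
            raise ValueError(
                f"state fractions sum to {s:.6f}; must be 1 within {_SUM_SLACK}"
            )
        return self

    def as_array(self, normalize: bool = False) -> np.ndarray:
        v = np.array([self.no_ptsd, self.non_severe, self.severe], dtype=float)
        return v / v.sum() if normalize else v

    def normalized(self) -> "StateDistribution":
        v = self.as_array(normalize=True)
        return StateDistribution(no_ptsd=v[0], non_severe=v[1], severe=v[2])

    def __getitem__(self, state: HealthState) -> float:
        return getattr(self, state.value)


class StateValues(BaseModel):
    """A scalar per alive state (costs in USD/month here)."""

    model_config = ConfigDict(frozen=True)

    no_ptsd: float
    non_severe: float
    severe: float

    def as_array(self) -> np.ndarray:
        return np.array([self.no_ptsd, self.non_severe, self.severe], dtype=float)

    def __getitem__(self, state: HealthState) -> float:
        return getattr(self, state.value)


class UtilityValues(StateValues):
    """EQ-5D-5L index per alive state; the index can be negative (worse than dead)."""

    no_ptsd: float = Field(ge=-1.0, le=1.0)
    non_severe: float = Field(ge=-1.0, le=1.0)
    severe: float = Field(ge=-1.0, le=1.0)


class CostParameters(BaseModel):
    """Session prices and per-state monthly costs, nominal USD.

    ``prep_session_cost`` and ``integration_session_cost`` are the full
    two-therapist 90-minute session prices; ``interventional_psychotherapy_cost``
    is the two-therapist 8-hour psychotherapy component of one interventional
    session (drug cost excluded).
    """

    model_config = ConfigDict(frozen=True)

    prep_session_cost: float = Field(ge=0.0)
    interventional_psychotherapy_cost: float = Field(ge=0.0)
    mdma_price_per_session: float = Field(ge=0.0)
    integration_session_cost: float = Field(ge=0.0)
    monthly_visit_cost: StateValues
    monthly_treatment_cost: StateValues

    @model_validator(mode="after")
    def _nonnegative_state_costs(self) -> "CostParameters":
        for name in ("monthly_visit_cost", "monthly_treatment_cost"):
            sv: StateValues = getattr(self, name)
            for state in ALIVE_STATES:
                if sv[state] < 0:
                    raise ValueError(f"{name}.{state.value} must be >= 0")
        return self


class ArmInputs(BaseModel):
    """Per-arm occupancy and utility inputs for both cycle blocks."""

    model_config = ConfigDict(frozen=True)

    cycle1_distribution: StateDistribution
    later_distribution: StateDistribution
    cycle1_utilities: UtilityValues
    later_utilities: UtilityValues

    def distribution(self, block: CycleBlock) -> StateDistribution:
        return (
            self.cycle1_distribution
            if block is CycleBlock.CYCLE_1
            else self.later_distribution
        )

    def utilities(self, block: CycleBlock) -> UtilityValues:
        return (
            self.cycle1_utilities
            if block is CycleBlock.CYCLE_1
            else self.later_utilities
        )

    # convenience aliases used throughout the tests / examples
    @property
    def cycle1(self) -> StateDistribution:
        return self.cycle1_distribution


class ScheduleParameters(BaseModel):
    """Horizon, discounting, willingness-to-pay, and the session schedule."""

    model_config = ConfigDict(frozen=True)

    horizon_years: int = Field(default=5, ge=1, le=25)
    discount_rate: float = Field(default=0.035, ge=0.0)
    wtp: float = Field(default=150_000.0, ge=0.0)
    treatment_period_months: int = Field(default=4, ge=0, le=12)
    n_prep_sessions: int = Field(default=3, ge=0)
    n_interventional_sessions: int = Field(default=3, ge=0)
    n_integration_sessions: int = Field(default=9, ge=0)
    n_therapists: int = Field(default=2, ge=1)
    base_session_minutes: float = Field(default=90.0, gt=0.0)
    interventional_minutes: float = Field(default=480.0, gt=0.0)


class MortalityParameters(BaseModel):
    """All-cause mortality expressed as a cumulative rate over a reference period."""

    model_config = ConfigDict(frozen=True)

    cumulative_rate: float = Field(default=0.0132, ge=0.0, lt=1.0)
    reference_years: int = Field(default=5, ge=1)


class ModelConfig(BaseModel):
    """Every numeric input of the analysis; the single source of truth downstream."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = 1
    baseline_age: float = Field(default=39.0, gt=0.0)
    arms: dict[Arm, ArmInputs]
    costs: CostParameters
    schedule: ScheduleParameters = ScheduleParameters()
    mortality: MortalityParameters = MortalityParameters()

    @model_validator(mode="after")
    def _both_arms_present(self) -> "ModelConfig":
        missing = [a.value for a in Arm if a not in self.arms]
        if missing:
            raise ValueError(f"arms missing required entries: {missing}")
        return self

    def arm(self, arm: Arm) -> ArmInputs:
        return self.arms[arm]

    def distribution(self, arm: Arm, block: CycleBlock) -> StateDistribution:
        return self.arms[arm].distribution(block)

    def utilities(self, arm: Arm, block: CycleBlock) -> UtilityValues:
        return self.arms[arm].utilities(block)

    def utility(self, arm: Arm, state: HealthState, block: CycleBlock) -> float:
        return self.arms[arm].utilities(block)[state]


def builtin_base_case() -> ModelConfig:
    """The published base case: 5-year horizon, 3.5% discounting, $150k WTP.

    Percentages are stored as printed fractions (79.39% -> 0.7939); utilities at
    full printed precision.  Occupancy rows sum to ~0.9976 as printed and are
    renormalized by the engine at consumption time.
    """
    return ModelConfig(
        arms={
            Arm.MDMA_AT: ArmInputs(
                cycle1_distribution=StateDistribution(
                    no_ptsd=0.7939, non_severe=0.0867, severe=0.1170
                ),
                later_distribution=StateDistribution(
                    no_ptsd=0.8289, non_severe=0.0983, severe=0.0702
                ),
                cycle1_utilities=UtilityValues(
                    no_ptsd=0.816101, non_severe=0.710804, severe=0.619287
                ),
                later_utilities=UtilityValues(
                    no_ptsd=0.821930, non_severe=0.714290, severe=0.612000
                ),
            ),
            Arm.PT: ArmInputs(
                cycle1_distribution=StateDistribution(
                    no_ptsd=0.4328, non_severe=0.2037, severe=0.3612
                ),
                later_distribution=StateDistribution(
                    no_ptsd=0.4534, non_severe=0.2116, severe=0.3325
                ),
                cycle1_utilities=UtilityValues(
                    no_ptsd=0.791415, non_severe=0.711006, severe=0.596565
                ),
                later_utilities=UtilityValues(
                    no_ptsd=0.790370, non_severe=0.729170, severe=0.603180
                ),
            ),
        },
        costs=CostParameters(
            prep_session_cost=442.0,
            interventional_psychotherapy_cost=2357.0,
            mdma_price_per_session=12_000.0,
            integration_session_cost=442.0,
            monthly_visit_cost=StateValues(no_ptsd=70.0, non_severe=112.0, severe=226.0),
            monthly_treatment_cost=StateValues(
                no_ptsd=203.0, non_severe=338.0, severe=283.0
            ),
        ),
        schedule=ScheduleParameters(),
        mortality=MortalityParameters(),
        baseline_age=39.0,
    )


def validate_config(config: ModelConfig) -> list[str]:
    """Soft checks beyond the hard invariants; returns human-readable warnings."""
    warnings: list[str] = []
    mv = config.costs.monthly_visit_cost
    if not (mv.severe >= mv.non_severe >= mv.no_ptsd):
        warnings.append(
            "monthly_visit_cost ordering severe >= non_severe >= no_ptsd does not hold"
        )
    return warnings


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _format_validation_error(err: ValidationError) -> str:
    parts = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        parts.append(f"{loc}: {e['msg']}")
    return "; ".join(parts)


def load_config(path: str | pathlib.Path) -> ModelConfig:
    """Load a YAML/JSON config; unspecified fields take base-case defaults.

    Raises :class:`ConfigFormatError` on parse failure (naming the line where
    the parser stopped) and :class:`ConfigValidationError` on invariant
    violations (naming the offending field and rule).
    """
    path = pathlib.Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            tree = json.loads(text)
        else:
            tree = yaml.safe_load(text)
    except json.JSONDecodeError as exc:
        raise ConfigFormatError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigFormatError(f"{path}: invalid YAML{where}: {exc}") from exc
    if tree is None:
        tree = {}
    if not isinstance(tree, Mapping):
        raise ConfigFormatError(f"{path}: top level must be a mapping")
    merged = _deep_merge(builtin_base_case().model_dump(mode="json"), tree)
    try:
        return ModelConfig.model_validate(merged)
    except ValidationError as exc:
        raise ConfigValidationError(
            f"{path}: {_format_validation_error(exc)}"
        ) from exc


def save_config(config: ModelConfig, path: str | pathlib.Path) -> None:
    """Write the config as YAML (or JSON if the suffix is .json).

    Floats are emitted with round-trippable decimal text, so save->load is an
    identity on every numeric field.
    """
    path = pathlib.Path(path)
    tree = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(tree, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(tree, sort_keys=False))
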