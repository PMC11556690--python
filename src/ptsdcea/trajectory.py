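"""Occupancy and survival schedules for the annual-cycle cohort model.

The trial pathway observes state occupancy at enrollment, the 4-month
post-treatment endpoint, and the ~17-month long-term follow-up.  The model
needs occupancy at the 1-year point for its first annual cycle; that point is
obtained by fitting a log model p(t) = a + b*ln(t) to the No-PTSD proportion
over time, reading it off at 12 months, and redistributing the gain relative
to the previous observed timepoint equally out of the Non-severe and Severe
states.  Cycles 2+ reuse the long-term follow-up occupancy directly.

Mortality enters as a cumulative rate over a reference period (1.32% over
5 years in the base case), converted to a constant annual death probability;
the survival weight for cycle t is start-of-cycle survival (1-p)^(t-1).
"""
from __future__ import annotations

import math
import pathlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_inputs import Arm, CycleBlock, ModelConfig, StateDistribution

__all__ = [
    "TimedDistribution",
    "OccupancySchedule",
    "annual_prob_from_cumulative",
    "fit_log_model",
    "estimate_cycle1_distribution",
    "build_schedule",
    "read_timepoint_series",
    "write_timepoint_series",
]

#: Enrollment (time 0) is mapped to this time for the log fit, since ln(0) is
#: undefined and the time origin of the published fit is not recoverable.
ENROLLMENT_FIT_MONTHS = 1.0


@dataclass(frozen=True)
class TimedDistribution:
    """State occupancy observed at a trial timepoint (months since enrollment)."""

    time_months: float
    distribution: StateDistribution

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ValueError("time_months must be >= 0")


@dataclass(frozen=True)
class OccupancySchedule:
    """Per-cycle occupancy (normalized) and survival weights for one arm."""

    distributions: tuple[StateDistribution, ...]
    survival: np.ndarray  # fraction alive during cycle t, t = 1..horizon
    annual_death_prob: float

    @property
    def horizon_years(self) -> int:
        return len(self.distributions)


def annual_prob_from_cumulative(cumulative_rate: float, reference_years: int) -> float:
    """Constant annual death probability p with 1-(1-p)^reference_years = cumulative_rate."""
    if not 0.0 <= cumulative_rate < 1.0:
        raise ValueError("cumulative_rate must be in [0, 1)")
    if reference_years < 1:
        raise ValueError("reference_years must be >= 1")
    return 1.0 - (1.0 - cumulative_rate) ** (1.0 / reference_years)


def fit_log_model(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares fit of p(t) = a + b*ln(t); returns (a, b).

    With exactly two points the fitted curve passes through both.
    """
    if len(points) < 2:
        raise ValueError("log-model fit needs at least 2 points")
    times = np.array([t for t, _ in points], dtype=float)
    props = np.array([p for _, p in points], dtype=float)
    if np.any(times <= 0):
        raise ValueError("all times must be > 0 (ln undefined otherwise)")
    b, a = np.polyfit(np.log(times), props, 1)
    return float(a), float(b)


def estimate_cycle1_distribution(
    series: Sequence[TimedDistribution],
    target_time: float = 12.0,
    enrollment_fit_months: float = ENROLLMENT_FIT_MONTHS,
) -> StateDistribution:
    """Occupancy at ``target_time`` via log-model extrapolation of the No-PTSD state.

    Fits p(t) = a + b*ln(t) to the No-PTSD proportions of ``series`` (a time of
    0 is mapped to ``enrollment_fit_months``), evaluates at ``target_time``, and
    distributes the gain over the previous observed timepoint equally out of the
    Non-severe and Severe states.  States clamped at zero trigger a
    renormalization; the result always satisfies the occupancy invariants.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 timepoints")
    times = [td.time_months for td in series]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("timepoint times must be strictly increasing")
    fit_points = [
        (td.time_months if td.time_months > 0 else enrollment_fit_months,
         td.distribution.no_ptsd)
        for td in series
    ]
    a, b = fit_log_model(fit_points)
    p_target = a + b * math.log(target_time)

    # previous observed timepoint = last one strictly before target_time
    prev_candidates = [td for td in series if td.time_months < target_time]
    if not prev_candidates:
        raise ValueError("target_time precedes every observed timepoint")
    prev = prev_candidates[-1].distribution
    gain = p_target - prev.no_ptsd

    raw = np.array(
        [prev.no_ptsd + gain, prev.non_severe - gain / 2.0, prev.severe - gain / 2.0]
    )
    raw = np.clip(raw, 0.0, None)
    raw = raw / raw.sum()
    return StateDistribution(no_ptsd=raw[0], non_severe=raw[1], severe=raw[2])


def build_schedule(config: ModelConfig, arm: Arm) -> OccupancySchedule:
    """Per-cycle normalized occupancy and survival weights over the horizon.

    Cycle 1 uses the arm's first-cycle distribution, cycles 2+ the long-term
    distribution; survival weight for cycle t is (1-p)^(t-1) with p converted
    from the configured cumulative mortality.
    """
    horizon = config.schedule.horizon_years
    p = annual_prob_from_cumulative(
        config.mortality.cumulative_rate, config.mortality.reference_years
    )
    c1 = config.distribution(arm, CycleBlock.CYCLE_1).normalized()
    later = config.distribution(arm, CycleBlock.CYCLES_2_PLUS).normalized()
    distributions = (c1,) + (later,) * (horizon - 1)
    survival = (1.0 - p) ** np.arange(horizon, dtype=float)
    return OccupancySchedule(
        distributions=distributions, survival=survival, annual_death_prob=p
    )


_SERIES_COLUMNS = ["arm", "time_months", "no_ptsd", "non_severe", "severe"]


def read_timepoint_series(path: str | pathlib.Path) -> dict[Arm, list[TimedDistribution]]:
    """Read per-arm timepoint occupancy from CSV (columns: arm, time_months, no_ptsd, non_severe, severe)."""
    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"timepoint CSV missing columns: {missing}")
    out: dict[Arm, list[TimedDistribution]] = {}
    for arm_label, group in df.groupby("arm"):
        arm = Arm(arm_label)
        group = group.sort_values("time_months")
        out[arm] = [
            TimedDistribution(
                time_months=float(row.time_months),
                distribution=StateDistribution(
                    no_ptsd=row.no_ptsd, non_severe=row.non_severe, severe=row.severe
                ),
            )
            for row in group.itertuples()
        ]
    return out


def write_timepoint_series(
    series: dict[Arm, Iterable[TimedDistribution]], path: str | pathlib.Path
) -> None:
    rows = [
        {
            "arm": arm.value,
            "time_months": td.time_months,
            "no_ptsd": td.distribution.no_ptsd,
            "non_severe": td.distribution.non_severe,
            "severe": td.distribution.severe,
        }
        for arm, tds in series.items()
        for td in tds
    ]
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)
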