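"""Deterministic (tornado), probabilistic (PSA/CEAC) and threshold-price analyses.

One-way sensitivity analysis reruns the full model with a single input moved
to (1 +/- variation) times its base value, everything else fixed; occupancy
fractions are varied with proportional renormalization of the complementary
states so each perturbed config is still a valid distribution.

The probabilistic analysis samples all inputs jointly — gamma for costs
(mean-preserving, default CV 0.10), beta for utilities and the cumulative
mortality rate (method of moments at the base mean), Dirichlet for each
occupancy block (concentration scaled to a target component SD) — reruns the
model per draw, and summarizes the incremental plane plus the
cost-effectiveness acceptability curve.  Sampling order is fixed by sorted
parameter id under a single seeded generator, so a given (seed, spec) pair is
bit-reproducible.

Threshold pricing exploits that the incremental cost is affine in the
medication price with slope equal to the number of interventional sessions:
the price at which the ICER equals a willingness-to-pay threshold is solved
in closed form, then verified by rerunning the model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_cea import discount_factor, run_cea
from .model_inputs import Arm, CycleBlock, ModelConfig

__all__ = [
    "TornadoEntry",
    "PsaSpec",
    "PsaSummary",
    "list_scalar_parameters",
    "get_parameter",
    "with_parameter",
    "run_owsa",
    "owsa_table",
    "run_psa",
    "threshold_price",
    "icer_price_curve",
]

_STATE_FIELDS = ("no_ptsd", "non_severe", "severe")

_COST_FIELDS = (
    "costs.prep_session_cost",
    "costs.interventional_psychotherapy_cost",
    "costs.mdma_price_per_session",
    "costs.integration_session_cost",
)


class ParameterError(KeyError):
    """The identifier does not address a scalar numeric field of ModelConfig."""


def list_scalar_parameters(config: ModelConfig) -> list[str]:
    """Every scalar input addressable by the sensitivity analyses, sorted."""
    params = list(_COST_FIELDS)
    for bucket in ("monthly_visit_cost", "monthly_treatment_cost"):
        params += [f"costs.{bucket}.{s}" for s in _STATE_FIELDS]
    for arm in Arm:
        for block in ("cycle1_utilities", "later_utilities"):
            params += [f"arms.{arm.value}.{block}.{s}" for s in _STATE_FIELDS]
        for block in ("cycle1_distribution", "later_distribution"):
            params += [f"arms.{arm.value}.{block}.{s}" for s in _STATE_FIELDS]
    params.append("mortality.cumulative_rate")
    return sorted(params)


def _resolve(tree: dict[str, Any], path: Sequence[str]) -> Any:
    node: Any = tree
    for key in path:
        if not isinstance(node, dict) or key not in node:
            raise ParameterError(".".join(path))
        node = node[key]
    return node


def get_parameter(config: ModelConfig, param_id: str) -> float:
    value = _resolve(config.model_dump(mode="json"), param_id.split("."))
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ParameterError(f"{param_id} is not a scalar numeric field")
    return float(value)


def with_parameter(config: ModelConfig, param_id: str, value: float) -> ModelConfig:
    """A copy of ``config`` with one scalar replaced.

    Occupancy components carry a renormalization rule: the complementary
    states are rescaled proportionally so the block's total mass is preserved.
    """
    path = param_id.split(".")
    tree = config.model_dump(mode="json")
    parent = _resolve(tree, path[:-1])
    leaf = path[-1]
    if not isinstance(parent, dict) or leaf not in parent:
        raise ParameterError(param_id)
    if len(path) >= 2 and path[-2].endswith("_distribution"):
        old = parent[leaf]
        total = sum(parent[s] for s in _STATE_FIELDS)
        rest = total - old
        if value > total:
            raise ValueError(f"{param_id}={value} exceeds the block's total mass {total}")
        scale = (total - value) / rest if rest > 0 else 0.0
        for s in _STATE_FIELDS:
            parent[s] = value if s == leaf else parent[s] * scale
    else:
        parent[leaf] = value
    return ModelConfig.model_validate(tree)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_or_nan(config: ModelConfig) -> float:
    _, _, cea = run_cea(config)
    return cea.icer if cea.icer is not None else float("nan")


def run_owsa(
    config: ModelConfig,
    parameters: Optional[Sequence[str]] = None,
    variation: float = 0.10,
) -> list[TornadoEntry]:
    """One-way sensitivity analysis over ``parameters`` at +/- ``variation``.

    Returns one entry per parameter, sorted by descending ICER spread (ties
    broken lexicographically by parameter id).
    """
    if parameters is None:
        parameters = list_scalar_parameters(config)
    entries = []
    for pid in parameters:
        base = get_parameter(config, pid)
        low, high = base * (1.0 - variation), base * (1.0 + variation)
        icer_low = _icer_or_nan(with_parameter(config, pid, low))
        icer_high = _icer_or_nan(with_parameter(config, pid, high))
        entries.append(
            TornadoEntry(
                parameter=pid,
                low_value=low,
                high_value=high,
                icer_low=icer_low,
                icer_high=icer_high,
            )
        )
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries


def owsa_table(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

#: Willingness-to-pay grid (USD/QALY) the acceptability curve is evaluated on.
CEAC_WTP_GRID = (0.0, 50_000.0, 100_000.0, 150_000.0, 200_000.0)


@dataclass(frozen=True)
class PsaSpec:
    """Sampling families and dispersions for the probabilistic analysis.

    Costs: gamma with the given coefficient of variation. Utilities: beta by
    method of moments at the base mean with the given SD (capped by the
    support). Occupancy blocks: Dirichlet with concentration scaled so the
    largest component SD equals ``distribution_sd``. Mortality: beta with
    SD = ``mortality_cv`` times the base rate. ``overrides`` maps a parameter
    id (or a distribution block id) to a replacement dispersion; 0 freezes it.
    """

    cost_cv: float = 0.10
    utility_sd: float = 0.05
    distribution_sd: float = 0.05
    mortality_cv: float = 0.10
    overrides: dict[str, float] = field(default_factory=dict)

    def dispersion(self, param_id: str, default: float) -> float:
        return self.overrides.get(param_id, default)


@dataclass(frozen=True)
class PsaSummary:
    n_iterations: int
    seed: int
    mean_cost_ref: float
    mean_cost_comp: float
    mean_qalys_ref: float
    mean_qalys_comp: float
    mean_incremental_cost: float
    sd_incremental_cost: float
    mean_incremental_qaly: float
    sd_incremental_qaly: float
    icer_of_means: float
    acceptability: dict[float, float]


def _sample_gamma(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv <= 0 or mean == 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size=n)


def _sample_beta(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd <= 0:
        return np.full(n, mean)
    if not 0.0 < mean < 1.0:
        # outside the beta support (e.g. a utility of exactly 0 or a negative
        # index): fall back to a clipped normal
        return np.clip(rng.normal(mean, sd, size=n), -1.0, 1.0)
    sd = min(sd, 0.95 * np.sqrt(mean * (1.0 - mean)))
    k = mean * (1.0 - mean) / sd**2 - 1.0
    return rng.beta(mean * k, (1.0 - mean) * k, size=n)


def _sample_dirichlet(
    rng: np.random.Generator, base: np.ndarray, sd: float, n: int
) -> np.ndarray:
    p = base / base.sum()
    if sd <= 0:
        return np.tile(p, (n, 1))
    c = max(np.max(p * (1.0 - p)) / sd**2 - 1.0, 1e-6)
    return rng.dirichlet(c * p, size=n)


def run_psa(
    config: ModelConfig,
    n_iterations: int = 5000,
    seed: int | None = None,
    distribution_spec: PsaSpec | None = None,
) -> tuple[pd.DataFrame, PsaSummary]:
    """Joint Monte-Carlo over all model inputs; returns (draws, summary).

    Each row of ``draws`` holds the sampled parameter values plus the
    incremental cost and QALY of that iteration (every sampled input set is a
    valid model: occupancy rows renormalized, utilities clamped to [-1, 1]).
    The summary ICER is the ratio of the MEAN increments, and the
    acceptability curve is the fraction of draws with positive net monetary
    benefit on the WTP grid (always including the configured threshold).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if seed is None:
        raise ValueError("run_psa requires an explicit seed")
    spec = distribution_spec or PsaSpec()
    rng = np.random.default_rng(seed)
    n = n_iterations
    sched = config.schedule

    # ---- sample every input, in sorted-parameter-id order ------------------
    samples: dict[str, np.ndarray] = {}
    simplexes: dict[str, np.ndarray] = {}

    scalar_ids = []
    for pid in _COST_FIELDS:
        scalar_ids.append((pid, "cost"))
    for bucket in ("monthly_visit_cost", "monthly_treatment_cost"):
        for s in _STATE_FIELDS:
            scalar_ids.append((f"costs.{bucket}.{s}", "cost"))
    for arm in Arm:
        for block in ("cycle1_utilities", "later_utilities"):
            for s in _STATE_FIELDS:
                scalar_ids.append((f"arms.{arm.value}.{block}.{s}", "utility"))
    scalar_ids.append(("mortality.cumulative_rate", "mortality"))
    simplex_ids = [
        f"arms.{arm.value}.{block}"
        for arm in Arm
        for block in ("cycle1_distribution", "later_distribution")
    ]

    plan: list[tuple[str, str]] = sorted(
        scalar_ids + [(pid, "simplex") for pid in simplex_ids]
    )
    for pid, kind in plan:
        if kind == "cost":
            base = get_parameter(config, pid)
            samples[pid] = _sample_gamma(rng, base, spec.dispersion(pid, spec.cost_cv), n)
        elif kind == "utility":
            base = get_parameter(config, pid)
            samples[pid] = np.clip(
                _sample_beta(rng, base, spec.dispersion(pid, spec.utility_sd), n),
                -1.0,
                1.0,
            )
        elif kind == "mortality":
            base = get_parameter(config, pid)
            sd = spec.dispersion(pid, spec.mortality_cv) * base
            samples[pid] = np.clip(_sample_beta(rng, base, sd, n), 0.0, 0.999999)
        else:
            arm_label, block = pid.split(".")[1:3]
            base = config.distribution(Arm(arm_label), _BLOCK_OF[block]).as_array()
            simplexes[pid] = _sample_dirichlet(
                rng, base, spec.dispersion(pid, spec.distribution_sd), n
            )

    # ---- vectorized cohort model over all draws ----------------------------
    horizon = sched.horizon_years
    disc = np.array([discount_factor(t, sched.discount_rate) for t in range(1, horizon + 1)])
    p_ann = 1.0 - (1.0 - samples["mortality.cumulative_rate"]) ** (
        1.0 / config.mortality.reference_years
    )
    surv = (1.0 - p_ann)[:, None] ** np.arange(horizon)[None, :]
    weights = surv * disc[None, :]  # (n, horizon)
    w1, wrest = weights[:, 0], weights[:, 1:].sum(axis=1)

    vis = np.column_stack(
        [samples[f"costs.monthly_visit_cost.{s}"] for s in _STATE_FIELDS]
    )
    trt = np.column_stack(
        [samples[f"costs.monthly_treatment_cost.{s}"] for s in _STATE_FIELDS]
    )

    totals: dict[Arm, np.ndarray] = {}
    qalys: dict[Arm, np.ndarray] = {}
    for arm in Arm:
        d1 = simplexes[f"arms.{arm.value}.cycle1_distribution"]
        d2 = simplexes[f"arms.{arm.value}.later_distribution"]
        u1 = np.column_stack(
            [samples[f"arms.{arm.value}.cycle1_utilities.{s}"] for s in _STATE_FIELDS]
        )
        u2 = np.column_stack(
            [samples[f"arms.{arm.value}.later_utilities.{s}"] for s in _STATE_FIELDS]
        )
        drug = samples["costs.mdma_price_per_session"] if arm is Arm.MDMA_AT else 0.0
        interv = (
            sched.n_prep_sessions * samples["costs.prep_session_cost"]
            + sched.n_interventional_sessions
            * (drug + samples["costs.interventional_psychotherapy_cost"])
            + sched.n_integration_sessions * samples["costs.integration_session_cost"]
        )
        visits = 12.0 * (w1 * np.sum(d1 * vis, axis=1) + wrest * np.sum(d2 * vis, axis=1))
        active1 = 12.0 - sched.treatment_period_months
        treatment = active1 * w1 * np.sum(d1 * trt, axis=1) + 12.0 * wrest * np.sum(
            d2 * trt, axis=1
        )
        totals[arm] = interv + visits + treatment
        qalys[arm] = w1 * np.sum(d1 * u1, axis=1) + wrest * np.sum(d2 * u2, axis=1)

    inc_cost = totals[Arm.MDMA_AT] - totals[Arm.PT]
    inc_qaly = qalys[Arm.MDMA_AT] - qalys[Arm.PT]

    draws = pd.DataFrame(samples)
    for pid, mat in simplexes.items():
        for j, s in enumerate(_STATE_FIELDS):
            draws[f"{pid}.{s}"] = mat[:, j]
    draws = draws[sorted(draws.columns)]
    draws["incremental_cost"] = inc_cost
    draws["incremental_qaly"] = inc_qaly

    wtp_grid = sorted(set(CEAC_WTP_GRID) | {float(sched.wtp)})
    acceptability = {
        w: float(np.mean(w * inc_qaly - inc_cost > 0)) for w in wtp_grid
    }
    mean_dq = float(inc_qaly.mean())
    summary = PsaSummary(
        n_iterations=n,
        seed=seed,
        mean_cost_ref=float(totals[Arm.MDMA_AT].mean()),
        mean_cost_comp=float(totals[Arm.PT].mean()),
        mean_qalys_ref=float(qalys[Arm.MDMA_AT].mean()),
        mean_qalys_comp=float(qalys[Arm.PT].mean()),
        mean_incremental_cost=float(inc_cost.mean()),
        sd_incremental_cost=float(inc_cost.std(ddof=1)) if n > 1 else 0.0,
        mean_incremental_qaly=mean_dq,
        sd_incremental_qaly=float(inc_qaly.std(ddof=1)) if n > 1 else 0.0,
        icer_of_means=float(inc_cost.mean() / mean_dq) if mean_dq != 0 else float("nan"),
        acceptability=acceptability,
    )
    return draws, summary


_BLOCK_OF = {
    "cycle1_distribution": CycleBlock.CYCLE_1,
    "later_distribution": CycleBlock.CYCLES_2_PLUS,
}


# --------------------------------------------------------------------------
# Threshold (value-based) pricing
# --------------------------------------------------------------------------


class NoFiniteThresholdError(ValueError):
    """The incremental QALY is non-positive: no finite price meets the threshold."""


_PRICE_PARAM = "costs.mdma_price_per_session"


def threshold_price(config: ModelConfig, wtp: float) -> float:
    """Maximum medication price per session with ICER(price) = ``wtp``.

    The incremental cost is affine in the price with slope equal to the number
    of interventional sessions, so the goal-seek has a closed form; the result
    is verified by rerunning the model (|ICER - wtp| < $1/QALY).
    """
    _, _, base = run_cea(config)
    if base.incremental_qaly <= 0:
        raise NoFiniteThresholdError(
            "incremental QALY <= 0 at the base configuration; no finite threshold price"
        )
    p0 = config.costs.mdma_price_per_session
    slope = config.schedule.n_interventional_sessions
    price = p0 + (wtp * base.incremental_qaly - base.incremental_cost) / slope
    _, _, check = run_cea(with_parameter(config, _PRICE_PARAM, price))
    if check.icer is None or abs(check.icer - wtp) >= 1.0:
        raise RuntimeError(
            f"goal-seek verification failed: ICER({price:.2f}) = {check.icer}"
        )
    return price


def icer_price_curve(
    config: ModelConfig, prices: Sequence[float]
) -> list[tuple[float, float]]:
    """ICER at each medication price (strictly increasing in price).

    Reports the signed cost/QALY ratio even where the reference arm dominates
    (negative incremental cost), so the curve stays defined across the grid.
    """
    out = []
    for price in prices:
        if price < 0:
            raise ValueError("prices must be >= 0")
        _, _, cea = run_cea(with_parameter(config, _PRICE_PARAM, price))
        ratio = (
            cea.incremental_cost / cea.incremental_qaly
            if cea.incremental_qaly != 0
            else float("nan")
        )
        out.append((float(price), float(ratio)))
    return out
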