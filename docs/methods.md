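# Methods

## Model structure and assumptions

The model is a cohort expectation over four mutually exclusive health states
(No PTSD, Non-severe PTSD, Severe PTSD, death) with annual cycles and a
maximum horizon of 25 years (base case 5). It is deliberately not a
microsimulation: occupancy per cycle is taken directly from two input
distributions — one for the first annual cycle (extrapolated to the 1-year
point from trial timepoints) and one reused for all later cycles (long-term
follow-up occupancy) — rather than from a transition matrix. This mirrors how
the analysis was parametrized: the data support state *prevalence* at
timepoints, not individual transition intensities.

Death is absorbing and carries no costs or utilities. Mortality is a single
5-year cumulative rate (1.32%, base case) shared by both arms, converted to a
constant annual probability p via 1 − (1 − p)^5 = 0.0132; no age-updated
life-table lookup is performed over the horizon (a deliberate simplification
at these short horizons and low rates).

### Conventions that matter numerically

* **Discounting**: d(t) = (1 + r)^−(t−1); the first cycle is undiscounted.
* **Survival weighting**: start-of-cycle survival, s(t) = (1 − p)^(t−1);
  cycle 1 fully alive. No half-cycle correction anywhere.
* **Occupancy normalization**: input occupancy rows are accepted if they sum
  to 1 within 1%, stored at their given precision, and renormalized exactly
  when the engine consumes them. Published occupancy tables printed to two
  decimals sum to ~99.76%; renormalizing reproduces the published QALY and
  cost totals to ≈0.03%, while consuming the raw rows leaves a ~0.25%
  shortfall. The low-level primitives (`cycle_utility`, `cycle_visit_cost`,
  `cycle_treatment_cost`) operate on the distribution exactly as passed;
  normalization happens once, in `build_schedule`.
* **Intervention cost**: charged once, undiscounted, at model start. The
  course is 3 preparation + 3 interventional + 9 integration sessions with
  two therapists; the comparator is the identical protocol with the
  medication price set to zero. Session prices are stored as the published
  two-therapist figures ($442 per 90-minute session, $2,357 per 8-hour
  session) rather than re-derived from a base rate, so course totals match
  the published arithmetic within $2; `session_cost` exists for users
  supplying their own single-therapist base rates.
* **Treatment-period exclusion**: regular PTSD treatment costs are excluded
  for the first `treatment_period_months` (default 4) of cycle 1 — other
  PTSD treatments were disallowed during the trial course. PTSD *visit*
  costs accrue for all 12 months of every cycle; this is the only convention
  under which the published 5-year visit totals are reproduced.
* **Log-model extrapolation**: the No-PTSD proportion is fitted as
  p(t) = a + b·ln(t) by least squares over the observed timepoints, with
  enrollment (t = 0) mapped to t = 1 month since ln 0 is undefined and the
  original fit's time origin is not recoverable; the mapping is an explicit
  argument so its influence can be probed. The fitted 12-month gain over the
  previous observed timepoint is removed half-and-half from the Non-severe
  and Severe states; if half the gain exceeds a state's occupancy the state
  is clamped at zero and the row renormalized (never triggered by the
  bundled inputs).
* **ICER reporting**: reported only in the NE/SW quadrants of the
  incremental plane; "dominant"/"dominated" flags otherwise, and a zero QALY
  increment yields an undefined flag rather than a division. Dollars are
  reported rounded to integers and QALYs to 3 decimals; all internal
  computation is double precision.

## Parameters

All base-case inputs live in `builtin_base_case()` and can be overridden via
YAML/JSON configs. The consequential ones:

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `schedule.horizon_years` | 5 | years | 1–25 supported |
| `schedule.discount_rate` | 0.035 | /year | applied to costs and QALYs |
| `schedule.wtp` | 150,000 | $/QALY | threshold for NMB/CEAC |
| `schedule.treatment_period_months` | 4 | months | treatment-cost exclusion, cycle 1 |
| `costs.mdma_price_per_session` | 12,000 | $ | the price assumption under study |
| `mortality.cumulative_rate` | 0.0132 | fraction/5 yr | both arms |
| occupancy & utilities | per arm × block | — | the published table values |

## Sensitivity analyses

**One-way (tornado)**: every scalar cost, utility, occupancy fraction, and
the mortality rate is varied to (1 ± 10%) of base, one at a time, with the
full model rerun. Varying one occupancy fraction requires a renormalization
rule; the complementary states are rescaled proportionally so the block's
total mass is preserved. Entries are sorted by descending ICER spread, ties
broken lexicographically.

**Probabilistic**: the published analysis states only that inputs were varied
"according to the assigned data distribution", so the families here are the
package's own choices, standard for this model class: gamma for
strictly-positive costs (mean-preserving, CV 0.10), beta by method of moments
for utilities (SD 0.05, capped by the support) and for the cumulative
mortality rate (CV 0.10), and Dirichlet for each occupancy block
(concentration scaled so the largest component SD ≈ 0.05). All are
mean-preserving at the base values, so the mean PSA increments converge to
the deterministic increments (verified at n = 50,000 within 3 Monte-Carlo
SEs). Published acceptability fractions cannot be reproduced exactly without
the original distribution spec and are treated as qualitative context only.
Sampling uses one seeded generator with parameters drawn in sorted-id order;
adding a parameter shifts draws only from its insertion point onward (a
documented limitation of this layout). The per-draw model is evaluated in
vectorized closed form — mathematically identical to `run_arm`, which the
degenerate (zero-dispersion) test pins down.

**Threshold pricing**: ΔCost is affine in the medication price with slope
equal to the number of interventional sessions, so ICER(P) = WTP is solved in
closed form and then verified by a full model rerun (|ICER − WTP| < $1/QALY,
enforced).

## The synthetic trial generator

`synthetic_trial` emulates the *structure* of the patient-level data the
model was parametrized from: per-patient CAPS-5 totals at enrollment /
4 months / 17 months, an adjudicated loss-of-diagnosis flag (generated as an
explicit boolean conditional on response rather than re-implemented DSM-5
criterion logic), EQ-5D-5L indices, and withdrawal/death events; plus the
classification rules mapping measurements to model states (response =
CAPS-5 decrease ≥ 10; withdrawal → Severe; loss of diagnosis → No PTSD;
baseline-moderate patients never classify as Severe while diagnosed).

Defaults were calibrated analytically so that the *expected* classified
occupancies at 4 and 17 months, pushed through the log-model extrapolation,
land on the published cycle-1 and cycles-2+ distributions: 30% of patients
moderate at baseline (CAPS-5 35 ± 6; severe 50 ± 8), mean 4-month CAPS-5
change −18.5 ± 12 (MDMA-AT) vs −8.8 ± 12 (PT), loss-of-diagnosis probability
given response 0.84 vs 0.757, additional follow-up drift −6 ± 6 vs +3 ± 6
(continued improvement under MDMA-AT, partial relapse under PT), 5%
withdrawal, 0.2% death. Per-state EQ-5D-5L means default to the published
per-arm values (SD 0.08). The generated CAPS-5 change distributions are
therefore calibration devices, not estimates of trial efficacy.

What the generator does **not** emulate: visit-level dosing and blinding,
adverse events, missingness/dropout patterns other than a single withdrawal
flag, correlation between severity and utility within state, or
between-trial heterogeneity. Passing recovery tests therefore show the
derivation *pipeline* is correct under the assumed data-generating process —
not that the pipeline is robust to real-data pathologies.

## Numerical and testing notes

* Deterministic headline results are exact to ≈0.3% of the published figures;
  the residual traces to inputs printed at 2-decimal precision and the
  unstated survival-weighting convention of the original spreadsheet, whose
  plausible variants bracket the published QALYs within ~0.3%.
* Test problem sizes: synthetic-recovery tests run 5,000 patients per arm;
  the mean-preservation PSA check runs 50,000 iterations (vectorized, <1 s);
  the full suite completes in a few seconds on one CPU.
* Degenerate inputs are handled explicitly: zero mortality (unit survival),
  zero discount (unit factors), zero-dispersion PSA (collapses to base case),
  empty states in derived utilities (flagged `None`, caller supplies
  fallback), occupancy clamping in the equal-split rule.

## Limitations

* Prevalence-based occupancy means no patient-level memory: the model cannot
  represent, e.g., differential mortality by state or response-dependent
  long-term trajectories beyond what the two occupancy blocks encode.
* Shared mortality across arms and states understates any survival benefit
  of remission; at 1.32%/5 yr this is numerically negligible.
* Payer-perspective direct costs only; no societal costs, adverse-event
  management, or retreatment.
* The 17-month follow-up occupancy is extrapolated to all later cycles;
  results beyond ~5 years lean heavily on that durability assumption.
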