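# ptsdcea

A cohort state-transition (Markov) cost-effectiveness model comparing
**MDMA-assisted therapy (MDMA-AT)** with **placebo-with-therapy (PT)** for
chronic PTSD of moderate or higher severity, from the US payer perspective.
It is written for health-economics analysts and methods researchers who want
a fully scriptable, reproducible implementation of this model class:
annual-cycle cohort expectations, QALY discounting, tornado and probabilistic
sensitivity analyses, and value-based threshold pricing.

## The model

Patients occupy one of four health states each annual cycle — *No PTSD*
(loss of DSM-5 diagnosis), *Non-severe PTSD* (treatment responders, CAPS-5
decrease ≥ 10 points, still diagnosed), *Severe PTSD* (non-responders and
treatment withdrawals), and *death*. Occupancy for the first cycle is
extrapolated from trial timepoints with a log model p(t) = a + b·ln(t);
later cycles reuse long-term follow-up occupancy. With survival weight
s(t) = (1 − p)^(t−1) (annual death probability p converted from a cumulative
rate), discount factor d(t) = (1 + r)^−(t−1), occupancy π(t) and per-state
utilities u and monthly costs c, each arm accrues

```
QALYs  = Σ_t s(t) · d(t) · π(t)ᵀu(t)
Costs  = C_intervention + Σ_t s(t) · d(t) · [12 · π(t)ᵀc_visit + m(t) · π(t)ᵀc_treat]
```

where m(t) is 12 except in cycle 1, where the months of the treatment course
are excluded from regular PTSD treatment costs. The headline outcome is the
incremental cost-effectiveness ratio

```
ICER = (Cost_MDMA-AT − Cost_PT) / (QALY_MDMA-AT − QALY_PT)
```

judged against a $150,000/QALY willingness-to-pay (WTP) threshold, with net
monetary benefit NMB = WTP·ΔQALY − ΔCost. Because the incremental cost is
affine in the medication price (slope = number of interventional sessions),
the maximum price at which ICER = WTP is solved in closed form and verified
by rerunning the model.

A synthetic patient-level trial generator (CAPS-5 trajectories, adjudicated
loss-of-diagnosis flags, EQ-5D-5L utilities, withdrawal/death events) plus the
state-classification rules make the full input-derivation pathway — cohort →
timepoint occupancy → log-model extrapolation → model config → ICER —
testable without the original (non-public) trial data.

## Worked example

```python
from ptsdcea import builtin_base_case, run_cea, threshold_price

config = builtin_base_case()          # published inputs, 5-year horizon
ref, comp, cea = run_cea(config)
print(f"MDMA-AT: ${ref.total_cost:,.0f}, {ref.qalys:.3f} QALYs")
print(f"PT:      ${comp.total_cost:,.0f}, {comp.qalys:.3f} QALYs")
print(f"ICER:    ${cea.icer:,.0f}/QALY")
print(f"Max price at $150k WTP: ${threshold_price(config, 150_000):,.0f}/session")
```

prints

```
MDMA-AT: $64,717, 3.691 QALYs
PT:      $33,116, 3.314 QALYs
ICER:    $83,819/QALY
Max price at $150k WTP: $20,317/session
```

i.e. MDMA-AT costs ~$31,600 more over five years, gains 0.377 QALYs, and is
cost-effective at the $150k threshold; the medication price could rise to
~$20.3k per session before the ICER reaches that threshold.

The same analyses are available from the shell:

```bash
ptsdcea run --out out/                    # traces + cea.json
ptsdcea owsa --variation 0.10 --out out/  # tornado table (±10%)
ptsdcea psa --n 5000 --seed 1 --out out/  # scatter draws, CEAC, summary
ptsdcea threshold --wtp 150000 --out out/
ptsdcea simulate --n-per-arm 200 --seed 1 --run-model --out out/
```

Every command writes a `run_manifest.json` (config hash, seeds, package
version) so a run can be reproduced exactly. Custom inputs go in a YAML/JSON
config (`--config`); omitted fields fall back to the built-in base case.

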