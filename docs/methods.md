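# Methods

## Model structure

The package implements a discrete-time cohort state-transition (Markov)
model with a one-month cycle. A model is specified as an ordered list
of health states — the order encodes disease severity, with the single
absorbing `Dead` state last — plus transition probabilities, treatment
strategies, an age/sex life table, and analysis settings. Structural
assumptions:

- **No remission.** Transitions may only point to equally- or
  more-severe states (later in the order). This encodes the clinical
  assumption that sustained recovery of kidney function is not
  expected; the validator rejects any backward transition.
- **Tunnel handover.** A state may carry a tunnel specification
  (`state → successor after k cycles`). Internally the state is
  expanded into *k* cycle-since-entry sub-states; survivors of the
  *k*-th sub-state move to the successor deterministically. The
  packaged model uses a 12-cycle tunnel for the first transplant year
  (different costs apply after year 1). Sub-states are collapsed for
  all reporting.
- **Mortality.** Background mortality comes from a life table of
  annual death probabilities by integer age and sex. Female and male
  hazards are mixed with the cohort's sex fraction *on the rate scale*,
  then combined with the state's excess annual mortality as independent
  competing hazards: r = −ln(1−q_bg) − ln(1−q_excess), per-cycle
  p = 1 − e^(−r/12). The cohort ages as `start_age + floor(cycle/12)`.
  A life table may end in a terminal row with q = 1, beyond which the
  whole row of every state moves to `Dead` (no one survives the
  terminal age); lookups clamp to the last row.

## Rates, probabilities and treatment effects

All timescale conversions assume a constant hazard within the period:
p = 1 − e^(−rt). Annual probabilities convert to monthly as
p₁₂ = 1 − (1−p)^(1/12). Treatment hazard ratios act multiplicatively
on the rate, p′ = 1 − (1−p)^HR, which keeps HR = 0 (elimination) and
HR > 1 coherent and makes HR application commute with timescale
conversion (both are rate-scale operations; property-tested). An HR
keyed on `(state, Dead)` scales that state's combined
background-plus-excess death rate — so direct mortality effects are
configurable per origin state, while the packaged treatments carry HRs
on CKD-origin progression only and any survival benefit emerges from
delayed entry into the high-mortality dialysis state.

## Accrual, discounting, half-cycle correction

Each cycle's cost and QALY accrual uses the *trapezoid* membership — the
average of start- and end-of-cycle occupancy — which is the half-cycle
correction variant that remains well-behaved when the cohort is
absorbed early; switching to first/last half-cycle weighting would be a
one-line change in `engine.run_cohort`. The accrual for cycle *t* is
discounted at the start-of-cycle factor (1+d)^(−t/12). Utilities are
stored as annualised weights and scaled by the cycle length; state
costs are stored per cycle. Productivity costs accrue only while the
cohort age is below the retirement age (default 65). A treatment's
one-off cost is booked at cycle 0, where the discount factor is 1. The
cohort loop stops at the horizon (capped at 1,200 cycles) or when
living mass falls below 1e−9.

## Engines

`run_cohort` propagates expected occupancy fractions
(o_{t+1} = o_t M_t) and reports total discounted cost and QALYs; per
state it reports expected person-years, and for the start state a
median sojourn read off the occupancy curve (which, with no re-entry,
is the survival function of time-to-leaving). `microsimulate` draws
individual trajectories from the same cycle-indexed matrices with the
identical accrual rule, so its per-patient means are unbiased for the
cohort totals (tested at n = 10,000 within 3 Monte-Carlo standard
errors); it yields full sojourn-time distributions, with medians
reported in years. All randomness flows through a
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
results. Matrices depend on cycle only through the cohort's integer
age, so one matrix is built and cached per model year.

## Comparison and dominance

ICER = ΔC/ΔE (reported as an undefined sentinel, never ±∞, when
ΔE = 0); NMB = λE − C; INMB = λΔE − ΔC. Absolute dominance requires
strictly higher cost *and* strictly fewer QALYs; ties on either axis
leave both strategies standing. Extended dominance is found by walking
the cost-sorted frontier and removing strategies whose ICER against the
cheaper neighbour exceeds the next ICER, until stable. All rows are
reported against the least-cost undominated strategy, matching the
presentation convention of published three-arm comparisons. Internal
arithmetic is unrounded; rounding is applied only in display/report
formatting.

## Probabilistic sensitivity analysis

Uncertainty specifications are moment-matched from a (mean, SE) pair:
beta for probabilities and utilities (α, β from mean/SE), gamma for
costs (shape = (mean/SE)², scale = SE²/mean), lognormal for hazard
ratios with log-mean = ln(HR) — the *median* reproduces the point HR;
the `se` field is the log-scale SD, defaulting to 0.15 where no CI is
available — and normal where symmetric noise is wanted. A zero SE
collapses to the point value. Each PSA iteration draws one parameter
set and evaluates *every* arm on it (common parameters across arms;
arms differ only by treatment effect and cost), using the deterministic
cohort engine — second-order uncertainty only. CEACs report the
fraction of iterations in which each arm attains the maximal NMB, with
ties split equally (measure-zero under continuous draws, deterministic
in degenerate tests); columns therefore sum to exactly 1. The default
willingness-to-pay grid is $0–150,000 in $1,000 steps.

## Threshold analysis

`two_way_threshold` varies one treatment's hazard ratio on every
CKD-tagged → ESRD-tagged transition together with its one-off cost,
holding everything else fixed, and records the winning strategy and the
treatment's NMB margin over the best alternative at fixed λ. Because
the one-off cost enters the total additively, a single cohort run per
HR covers the whole cost axis. The grid is evaluated at point estimates
(deterministic), matching how such decision surfaces are usually
presented. `extract_boundary` interpolates, per HR, the cost at which
the margin crosses zero; HRs where the treatment never wins are
omitted, and a boundary beyond the cost grid is reported as infinite.
Default grids: HR 0–1 in steps of 0.05, cost $0–80,000 in steps of
$2,500 (bracketing the landmarks of interest).

## Packaged DKD model and data provenance

States: `CKD` (stages 3–4 merged, since the underlying evidence pools
them — the engine accepts any split), `ESRD1` dialysis, `ESRD2`/
`ESRD2.2` transplant year 1 / later, `Dead`. Scenarios toggle start age
(71 → 40), sex mix (0/0.5/1 female), country cost column and discount
rate (Italy 3%, UK 3.5%, Ireland 4%). Every input row in
`src/dkdcea/data/*.csv` carries a provenance field. Values printed in
the source study body are used as-is: start age 71, λ = $47,000/QALY,
discount rates, monthly cycle, 100-year horizon, the MSC progression HR
0.83, and the ≈$80,000/yr dialysis cost anchor. All other costs,
utilities, transition probabilities and the SGLT2i effect (HR 0.66 on
progression) are synthetic placeholders chosen once to be clinically
plausible and to reproduce the study's *qualitative* results — cost
order SGLT2i < MSC < UC with SGLT2i dominant, MSC cheaper and more
effective than usual care, Italy's pricier SGLT2i putting MSC on the
frontier — but not its exact totals, which depend on unpublished
supplementary inputs. The packaged life table is a synthetic Gompertz
schedule (hazard doubling every 8 years, male q(71) = 0.023, female
rates 0.75× male, terminal age 110). The fixture's default PSA
specifications use a relative SE of 0.15.

## Synthetic model generator

`synthetic_data.generate_parameter_set(seed, …)` emits random, always
valid specifications for property testing: utilities strictly
decreasing along the severity order (a structural guarantee of the
generator; the packaged DKD model instead uses realistic transplant
utilities above dialysis), CKD costs strictly increasing with severity
and dialysis the costliest state, annual progression probabilities
within (0, 0.3), a Gompertz life table, and two treatment archetypes —
a one-off "CellTx" arm (HR 0.70–0.90) and a per-cycle "DrugTx" arm (HR
0.60–0.78) — whose defaults land near cost-effectiveness indifference
at λ = $47,000 so acceptability and threshold tests are informative.
Generated data emulate the *statistical shape* of real inputs, not
their correlations or any real population's mortality, so passing
property tests demonstrate internal consistency of the machinery, not
external validity of any particular parameterisation.

## Problem sizes and numerical tolerances

Row-stochasticity is enforced to 1e−12, trace mass conservation to
1e−10, and the cohort engine matches an exhaustive path-enumeration
oracle to 1e−9 on small models. The test suite and the acceptance
script use: microsimulation n = 10,000 (engine cross-check) and 20,000
(sojourn medians), PSA n = 5,000 (mean-recovery property, with 3%
symmetric normal noise) and 2,000 (fixture acceptability summary) —
sizes chosen to keep Monte-Carlo error well inside the 3-standard-error
bands while the full suite runs in well under a minute of compute for
the deterministic parts.

## Known limitations

- No adverse-event, cardiovascular or body-weight pathways; treatment
  effects are confined to the specified transition HRs.
- No correlated parameter sampling and no value-of-information
  measures (EVPI/EVSI) in the PSA.
- Discrete monthly cycles only; no continuous-time solver and no
  within-cycle event sequencing beyond the trapezoid correction.
- Memory is limited to the transplant tunnel; all other transitions
  are Markovian in the current state.
- Currency conversion and the meta-analytic pooling of literature
  inputs are upstream data-preparation steps, outside the model.
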