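# dkdcea

A Markov state-transition cost-effectiveness model for therapies in
diabetic kidney disease (DKD), written for health economists and
modellers who want a scriptable, reproducible alternative to spreadsheet
or GUI decision-tree tools.

The packaged model compares three strategies for patients with CKD
stages 3–4 attributable to type 2 diabetes:

- **Usual care (UC)** — supportive management only;
- **SGLT2i** — a monthly-cost oral drug with a hazard ratio < 1 on
  progression to end-stage renal disease (ESRD);
- **MSC** — a one-off mesenchymal stromal cell therapy, modelled as a
  hazard ratio (point value 0.83) on progression to ESRD.

The engine itself is generic: any severity-ordered state list,
transition set and treatment definitions can be supplied via a YAML
configuration or built programmatically.

## The model

Health states `CKD → ESRD1 (dialysis) → ESRD2 (transplant, year 1) →
ESRD2.2 (transplant, later years) → Dead` evolve in monthly cycles over
a 100-year horizon (or until the cohort is extinct). Progression is
irreversible (no remission). Transplant year 1 is a 12-cycle tunnel
that hands over to the later-years state automatically.

Key mechanics:

- Annual probabilities convert to monthly via the constant-hazard map
  *p*₁₂ = 1 − (1 − *p*)^(1/12); treatment effects act multiplicatively
  on the hazard, *p*′ = 1 − (1 − *p*)^HR, so HR = 0 eliminates a
  transition and effects commute with timescale conversion.
- Death combines an age/sex life table with state-specific excess
  mortality as independent competing hazards (rates add).
- Costs (healthcare + lost productivity while below retirement age, the
  societal perspective) and QALYs accrue with a trapezoid half-cycle
  correction and annual discounting (3% base case).
- Strategies are compared by ICER = ΔC/ΔE and net monetary benefit
  NMB = λ·E − C at willingness-to-pay λ = $47,000/QALY, with
  absolute/extended dominance classified on the cost-effectiveness
  frontier.
- Probabilistic sensitivity analysis draws inputs from moment-matched
  beta (probabilities, utilities), gamma (costs) and lognormal (hazard
  ratios) distributions — one common draw per iteration across all
  arms — and summarises as cost-effectiveness acceptability curves.
- Two-way threshold analysis maps the winning strategy over a grid of
  MSC effect (HR) × dose cost and extracts the indifference boundary.

**Data provenance.** Only a handful of the source study's inputs are
printed in its body (start age 71, discount rates, λ, the MSC HR 0.83,
the ≈$80k/yr dialysis cost anchor). The remaining packaged inputs are
clearly-marked synthetic placeholders with the correct structure (see
the `provenance` column in `src/dkdcea/data/*.csv`), so the shipped
model reproduces the study's qualitative patterns, not its exact
totals. Substituting measured values is a data edit, not a code edit.

## Worked example

```python
from dkdcea import classify_dominance, comparison_table, dkd_fixture, evaluate_arms

ps = dkd_fixture("base")                 # age 71, 3% discount, λ = $47k
rows = classify_dominance(evaluate_arms(ps), wtp=ps.settings.wtp)
print(comparison_table(rows).round(2).to_string(index=False))
```

prints

```
  strategy      cost  qaly            comparison   d_cost  d_qaly      icer      inmb     dominance
    SGLT2i 284863.14  6.33                            NaN     NaN       NaN       NaN   undominated
       MSC 295037.93  6.18        MSC vs. SGLT2i 10174.79   -0.15 -69419.01 -17063.61 abs_dominated
Usual Care 295997.08  6.05 Usual Care vs. SGLT2i 11133.93   -0.28 -39931.59 -24238.71 abs_dominated
```

SGLT2i is least costly *and* most effective, so it absolutely dominates
both alternatives; MSC is nonetheless cheaper and more effective than
usual care. A negative INMB is the monetary value lost per patient by
choosing that strategy over the comparator at λ = $47,000/QALY.

More narrative walk-throughs live in `examples/` (microsimulated
sojourn times, acceptability curves, the threshold boundary, synthetic
model generation), and the same analyses are available from a shell:

```bash
dkdcea run --scenario base --out-dir results/
dkdcea psa --scenario base --n-iterations 1000 --seed 1 --out-dir results/
dkdcea threshold --scenario base --out-dir results/
```

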