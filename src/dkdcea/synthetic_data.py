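"""Random, structurally valid model specifications for testing.

``generate_parameter_set`` emits a complete chronic-progressive-disease
model with the same statistical shape as the packaged DKD inputs:
severity-ordered states with strictly decreasing utilities and rising
healthcare costs (dialysis the most expensive state overall), annual
progression probabilities in (0, 0.3), a Gompertz background life table
(hazard doubling roughly every 8 years), and two treatment strategies —
a one-off (cell-therapy-like) arm and a per-cycle (drug-like) arm, both
with progression hazard ratios below 1.  Defaults put the two arms near
cost-effectiveness indifference at the $47,000/QALY threshold so that
acceptability-curve and threshold analyses on generated sets are
informative rather than degenerate.

``generate_psa_specs`` attaches moment-matched uncertainty distributions
to every utility, probability, cost and hazard ratio of a set.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import (
    AnalysisSettings,
    DistributionSpec,
    HealthState,
    LifeTable,
    ParameterSet,
    TransitionSpec,
    TreatmentDefinition,
    TunnelSpec,
)

__all__ = ["generate_parameter_set", "generate_psa_specs", "gompertz_life_table"]


def gompertz_life_table(
    doubling_years: float = 8.0,
    anchor_age: float = 71.0,
    anchor_q_male: float = 0.023,
    female_factor: float = 0.75,
    min_age: int = 30,
    terminal_age: int = 110,
) -> LifeTable:
    """Synthetic background-mortality table with exponentially rising
    hazard (rate doubling every ``doubling_years``), calibrated so the
    male annual death probability at ``anchor_age`` equals
    ``anchor_q_male``; the final row has q = 1 (terminal age)."""
    b = math.log(2.0) / doubling_years
    a = anchor_q_male / math.exp(b * anchor_age)
    ages = list(range(min_age, terminal_age + 1))
    qm, qf = [], []
    for age in ages:
        rm = a * math.exp(b * age)
        qm.append(1.0 if age == terminal_age else -math.expm1(-rm))
        qf.append(1.0 if age == terminal_age else -math.expm1(-female_factor * rm))
    return LifeTable(ages, qf, qm)


def generate_parameter_set(
    seed: int,
    n_ckd_states: int = 1,
    severity_cost_gradient: float = 1.6,
    utility_decrement: float = 0.08,
    start_age: float = 71.0,
    horizon_years: float = 100.0,
) -> ParameterSet:
    """Draw a random, valid model specification.

    States (in severity order): ``CKD_1 … CKD_n``, ``Dialysis``,
    ``KTx_year1`` (12-cycle tunnel), ``KTx_later``, ``Dead``.  The
    construction guarantees every structural invariant — utilities
    strictly decreasing with severity, dialysis the costliest state,
    per-cycle outgoing probabilities summing below 1 — for any seed.
    """
    if n_ckd_states < 1:
        raise ValueError("n_ckd_states must be >= 1")
    rng = np.random.default_rng(seed)

    ckd_names = [f"CKD_{i + 1}" for i in range(n_ckd_states)]
    states = []

    u = rng.uniform(0.78, 0.85)
    # annual healthcare cost of the first CKD stage, around $20k
    cost = rng.uniform(16_000.0, 24_000.0)
    ckd_costs = []
    for i, name in enumerate(ckd_names):
        states.append(
            HealthState(
                name=name,
                utility=round(u, 4),
                cost_healthcare=cost / 12.0,
                cost_productivity=rng.uniform(6_000.0, 14_000.0) / 12.0,
                excess_mortality_annual=rng.uniform(0.01, 0.05),
                tags=frozenset({"CKD"}),
            )
        )
        ckd_costs.append(cost)
        u -= utility_decrement * rng.uniform(0.8, 1.2)
        cost *= severity_cost_gradient * rng.uniform(0.9, 1.1)

    u_dial = min(u - utility_decrement * rng.uniform(0.8, 1.2), 0.65)
    u_dial = max(u_dial, 0.40)
    ktx_later_cost = max(ckd_costs) * 1.1
    ktx1_cost = ktx_later_cost * rng.uniform(2.5, 3.5)
    dial_cost = max(ktx1_cost * rng.uniform(1.05, 1.3), 80_000.0 * rng.uniform(0.9, 1.2))

    states.append(
        HealthState(
            "Dialysis", utility=round(u_dial, 4), cost_healthcare=dial_cost / 12.0,
            cost_productivity=rng.uniform(12_000.0, 20_000.0) / 12.0,
            excess_mortality_annual=rng.uniform(0.08, 0.16), tags=frozenset({"ESRD"}),
        )
    )
    # utilities stay strictly decreasing along the state order — a
    # structural guarantee for generated sets (the packaged DKD model
    # uses clinically realistic transplant utilities above dialysis)
    u_ktx1 = max(u_dial - utility_decrement * rng.uniform(0.2, 0.5), 0.32)
    u_ktx_later = max(u_ktx1 - utility_decrement * rng.uniform(0.1, 0.3), 0.30)
    states.append(
        HealthState(
            "KTx_year1", utility=round(u_ktx1, 4),
            cost_healthcare=ktx1_cost / 12.0,
            cost_productivity=rng.uniform(8_000.0, 16_000.0) / 12.0,
            excess_mortality_annual=rng.uniform(0.03, 0.07), tags=frozenset({"ESRD"}),
        )
    )
    states.append(
        HealthState(
            "KTx_later", utility=round(u_ktx_later, 4),
            cost_healthcare=ktx_later_cost / 12.0,
            cost_productivity=rng.uniform(4_000.0, 10_000.0) / 12.0,
            excess_mortality_annual=rng.uniform(0.01, 0.05), tags=frozenset({"ESRD"}),
        )
    )
    states.append(HealthState("Dead", utility=0.0, is_absorbing=True))

    transitions = []
    for i in range(n_ckd_states - 1):
        transitions.append(
            TransitionSpec(ckd_names[i], ckd_names[i + 1], rng.uniform(0.10, 0.28))
        )
    last_ckd = ckd_names[-1]
    transitions.append(TransitionSpec(last_ckd, "Dialysis", rng.uniform(0.03, 0.09)))
    transitions.append(TransitionSpec(last_ckd, "KTx_year1", rng.uniform(0.002, 0.008)))
    transitions.append(TransitionSpec("Dialysis", "KTx_year1", rng.uniform(0.02, 0.06)))

    progression = [(last_ckd, "Dialysis"), (last_ckd, "KTx_year1")]
    cell_arm = TreatmentDefinition(
        name="CellTx",
        one_off_cost=rng.uniform(8_000.0, 20_000.0),
        hazard_ratios={k: rng.uniform(0.70, 0.90) for k in progression},
    )
    drug_arm = TreatmentDefinition(
        name="DrugTx",
        per_cycle_cost=rng.uniform(30.0, 80.0),
        cost_state_tags=frozenset({"CKD"}),
        hazard_ratios={k: rng.uniform(0.60, 0.78) for k in progression},
    )

    settings = AnalysisSettings(
        start_age=start_age,
        horizon_years=horizon_years,
        discount_rate_annual=0.03,
        wtp=47_000.0,
        sex_mix=0.5,
        seed=seed,
    )
    return ParameterSet(
        states=states,
        transitions=transitions,
        treatments=[cell_arm, drug_arm],
        life_table=gompertz_life_table(),
        settings=settings,
        tunnels=[TunnelSpec("KTx_year1", "KTx_later", cycles=12)],
    )


def generate_psa_specs(ps: ParameterSet, rel_se: float = 0.1, seed: int = 0) -> list:
    """Moment-matched uncertainty specs for every tunable parameter of
    ``ps``: beta for utilities, transition probabilities and excess
    mortality; gamma for positive costs; lognormal for hazard ratios.
    SE = ``rel_se`` × point value (log-scale SD = ``rel_se`` for HRs)."""
    if not 0.0 < rel_se < 0.5:
        raise ValueError("rel_se must be in (0, 0.5)")
    specs = []
    for s in ps.states:
        if s.is_absorbing:
            continue
        if 0.0 < s.utility < 1.0:
            specs.append(
                DistributionSpec(
                    f"state:{s.name}.utility", "beta", s.utility, rel_se * s.utility
                )
            )
        if s.cost_healthcare > 0:
            specs.append(
                DistributionSpec(
                    f"state:{s.name}.cost_healthcare", "gamma", s.cost_healthcare,
                    rel_se * s.cost_healthcare,
                )
            )
        if s.cost_productivity > 0:
            specs.append(
                DistributionSpec(
                    f"state:{s.name}.cost_productivity", "gamma", s.cost_productivity,
                    rel_se * s.cost_productivity,
                )
            )
        if s.excess_mortality_annual > 0:
            specs.append(
                DistributionSpec(
                    f"state:{s.name}.excess_mortality_annual", "beta",
                    s.excess_mortality_annual, rel_se * s.excess_mortality_annual,
                )
            )
    for t in ps.transitions:
        if 0.0 < t.probability < 1.0:
            specs.append(
                DistributionSpec(
                    f"transition:{t.from_state}->{t.to_state}.probability", "beta",
                    t.probability, rel_se * t.probability,
                )
            )
    for tr in ps.treatments:
        for (a, b), hr in tr.hazard_ratios.items():
            if hr > 0:
                specs.append(
                    DistributionSpec(
                        f"treatment:{tr.name}.hr:{a}->{b}", "lognormal", hr, rel_se
                    )
                )
    return specs
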