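"""Shared builders: flat life tables, small toy models, and an
independent path-enumeration oracle for cohort totals."""

from __future__ import annotations

import numpy as np
import pytest

from dkdcea.parameters import (
    AnalysisSettings,
    HealthState,
    LifeTable,
    ParameterSet,
    TransitionSpec,
    TreatmentDefinition,
)


def flat_life_table(q: float = 0.0, min_age: int = 30, max_age: int = 120) -> LifeTable:
    """Constant annual background mortality with a terminal q=1 row."""
    ages = list(range(min_age, max_age + 1))
    qs = [q] * (len(ages) - 1) + [1.0]
    return LifeTable(ages, qs, qs)


def toy_parameter_set(
    n_alive: int = 2,
    probs: dict | None = None,
    utilities=None,
    costs=None,
    horizon_years: float = 0.5,
    discount: float = 0.0,
    treatments=(),
    background_q: float = 0.0,
    start_age: float = 50.0,
    retirement_age: float = 200.0,
    productivity=None,
) -> ParameterSet:
    """Small chain model: states S0..S{n-1} then Dead, with explicit
    per-cycle transition probabilities ``probs[(i, j)]``."""
    names = [f"S{i}" for i in range(n_alive)] + ["Dead"]
    utilities = utilities if utilities is not None else [0.8] * n_alive
    costs = costs if costs is not None else [0.0] * n_alive
    productivity = productivity if productivity is not None else [0.0] * n_alive
    states = [
        HealthState(
            names[i], utility=utilities[i], cost_healthcare=costs[i],
            cost_productivity=productivity[i], tags=frozenset({"alive"}),
        )
        for i in range(n_alive)
    ]
    states.append(HealthState("Dead", utility=0.0, is_absorbing=True))
    transitions = [
        TransitionSpec(names[i], names[j], p, timescale="per_cycle")
        for (i, j), p in (probs or {}).items()
    ]
    return ParameterSet(
        states=states,
        transitions=transitions,
        treatments=list(treatments),
        life_table=flat_life_table(background_q),
        settings=AnalysisSettings(
            horizon_years=horizon_years,
            discount_rate_annual=discount,
            start_age=start_age,
            retirement_age=retirement_age,
        ),
    )


def random_toy(rng: np.random.Generator, n_alive: int, n_cycles: int) -> tuple:
    """Random valid toy model plus a random treatment arm."""
    probs = {}
    for i in range(n_alive):
        targets = list(range(i + 1, n_alive + 1))  # forward only, incl. Dead
        raw = rng.uniform(0.02, 0.3, size=len(targets))
        raw *= rng.uniform(0.3, 0.85) / raw.sum()
        for j, p in zip(targets, raw):
            probs[(i, j)] = float(p)
    treatment = TreatmentDefinition(
        name="T",
        one_off_cost=float(rng.uniform(0, 500)),
        per_cycle_cost=float(rng.uniform(0, 50)),
        cost_state_tags=frozenset({"alive"}),
        hazard_ratios={
            (f"S{i}", f"S{j}"): float(rng.uniform(0.4, 1.1))
            for (i, j) in probs
            if j < n_alive
        },
    )
    ps = toy_parameter_set(
        n_alive=n_alive,
        probs=probs,
        utilities=list(rng.uniform(0.3, 1.0, n_alive)),
        costs=list(rng.uniform(0, 1000, n_alive)),
        productivity=list(rng.uniform(0, 200, n_alive)),
        horizon_years=n_cycles / 12.0,
        discount=float(rng.choice([0.0, 0.03, 0.05])),
        treatments=[treatment],
    )
    return ps, treatment


def enumerate_cohort_totals(ps: ParameterSet, treatment=None) -> tuple:
    """Independent oracle: exhaustive enumeration of all state paths.

    Rebuilds the per-cycle matrix directly from the specification
    (per-cycle probabilities, hazard ratios as 1-(1-p)^hr, residual
    self-loop) and sums discounted trapezoid accruals over every path,
    weighted by path probability.  Only valid for toy models with zero
    background/excess mortality, per-cycle timescales and no tunnels.
    """
    names = ps.state_names
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    hrs = treatment.hazard_ratios if treatment else {}
    M = np.zeros((n, n))
    for t in ps.transitions:
        assert t.timescale == "per_cycle"
        p = t.probability
        hr = hrs.get((t.from_state, t.to_state))
        if hr is not None:
            p = 1.0 - (1.0 - p) ** hr
        M[idx[t.from_state], idx[t.to_state]] += p
    for i in range(n):
        M[i, i] = 1.0 - M[i].sum() if not ps.states[i].is_absorbing else 1.0

    cpy = ps.settings.cycles_per_year
    n_cycles = round(ps.settings.horizon_years * cpy)
    d = ps.settings.discount_rate_annual
    u = np.array([s.utility / cpy for s in ps.states])
    c = np.array([s.cost_healthcare + s.cost_productivity for s in ps.states])
    if treatment is not None:
        c = c + np.array(
            [
                treatment.per_cycle_cost if (s.tags & treatment.cost_state_tags) else 0.0
                for s in ps.states
            ]
        )

    total_cost = total_qaly = 0.0
    stack = [(0, 1.0, 0.0, 0.0)]  # (state, prob, cost so far, qaly so far)
    for t in range(n_cycles):
        df = (1.0 + d) ** (-t / cpy)
        nxt = []
        for s, p, acc_c, acc_q in stack:
            for s2 in range(n):
                p2 = p * M[s, s2]
                if p2 == 0.0:
                    continue
                nxt.append(
                    (
                        s2,
                        p2,
                        acc_c + 0.5 * (c[s] + c[s2]) * df,
                        acc_q + 0.5 * (u[s] + u[s2]) * df,
                    )
                )
        stack = nxt
    for s, p, acc_c, acc_q in stack:
        total_cost += p * acc_c
        total_qaly += p * acc_q
    if treatment is not None:
        total_cost += treatment.one_off_cost
    return total_cost, total_qaly


@pytest.fixture(scope="session")
def synth_ps():
    from dkdcea.synthetic_data import generate_parameter_set

    return generate_parameter_set(seed=0)


@pytest.fixture(scope="session")
def dkd_base():
    from dkdcea.parameters import dkd_fixture

    return dkd_fixture("base")
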