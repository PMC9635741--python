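"""Model specification: health states, transitions, treatments, settings.

A :class:`ParameterSet` is the complete description of a discrete-time
state-transition (Markov) cost-effectiveness model: an ordered list of
health states (the ordering encodes disease severity), transition
probabilities between them, treatment strategies expressed as costs plus
hazard ratios on named transitions, an age/sex life table for background
mortality, analysis settings (cycle length, horizon, discounting,
willingness-to-pay), and optional uncertainty distributions for
probabilistic sensitivity analysis.

The packaged diabetic-kidney-disease (DKD) model — CKD stages 3–4
progressing to renal replacement therapy (dialysis or kidney transplant)
and death — is exposed through :func:`dkd_fixture`.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "HealthState",
    "TransitionSpec",
    "TunnelSpec",
    "TreatmentDefinition",
    "AnalysisSettings",
    "DistributionSpec",
    "LifeTable",
    "ParameterSet",
    "validate",
    "dkd_fixture",
    "DKD_SCENARIOS",
]


@dataclass(frozen=True)
class HealthState:
    """One Markov health state.

    Costs are stored per model cycle (monthly for a 1-month cycle);
    ``utility`` is the annualised utility weight — the engine scales it by
    the cycle length when accruing QALYs.  ``excess_mortality_annual`` is
    the disease-specific annual death probability added (on the rate
    scale) to background life-table mortality.
    """

    name: str
    utility: float
    cost_healthcare: float = 0.0
    cost_productivity: float = 0.0
    excess_mortality_annual: float = 0.0
    is_absorbing: bool = False
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class TransitionSpec:
    """A transition probability between two named states.

    ``timescale`` is ``"annual"`` (converted to per-cycle by the engine)
    or ``"per_cycle"``.
    """

    from_state: str
    to_state: str
    probability: float
    timescale: str = "annual"


@dataclass(frozen=True)
class TunnelSpec:
    """Deterministic handover: occupants of ``state`` move to
    ``successor`` after ``cycles`` cycles since entry (conditional on
    surviving).  Realised internally as tunnel sub-states."""

    state: str
    successor: str
    cycles: int = 12


@dataclass(frozen=True)
class TreatmentDefinition:
    """A strategy: treatment costs plus hazard ratios on named transitions.

    ``one_off_cost`` is booked once at cycle 0; ``per_cycle_cost`` accrues
    while the cohort occupies any state carrying a tag in
    ``cost_state_tags``.  ``hazard_ratios`` maps ``(from_state, to_state)``
    to a multiplicative effect on that transition's rate; a key with
    ``to_state == "Dead"`` (the absorbing state) scales the combined
    background-plus-excess death rate out of ``from_state``.  HR = 1 is no
    effect, HR = 0 eliminates the transition.
    """

    name: str
    one_off_cost: float = 0.0
    per_cycle_cost: float = 0.0
    cost_state_tags: frozenset = field(default_factory=frozenset)
    hazard_ratios: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "cost_state_tags", frozenset(self.cost_state_tags))
        object.__setattr__(
            self, "hazard_ratios", {tuple(k): float(v) for k, v in self.hazard_ratios.items()}
        )


@dataclass(frozen=True)
class AnalysisSettings:
    cycle_length_months: int = 1
    horizon_years: float = 100.0
    discount_rate_annual: float = 0.03
    wtp: float = 47_000.0
    start_age: float = 71.0
    sex_mix: float = 0.5  # fraction female
    retirement_age: float = 65.0
    seed: int = 0

    @property
    def cycles_per_year(self) -> int:
        return round(12 / self.cycle_length_months)


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution for one parameter, moment-matched.

    ``target`` is a parameter path:

    - ``state:<name>.<field>`` for utility / cost_healthcare /
      cost_productivity / excess_mortality_annual,
    - ``transition:<from>-><to>.probability``,
    - ``treatment:<name>.one_off_cost`` / ``.per_cycle_cost``,
    - ``treatment:<name>.hr:<from>-><to>``.

    ``family`` ∈ {beta, gamma, lognormal, normal}.  ``mean``/``se`` are the
    target mean and standard error; for ``lognormal`` (used for hazard
    ratios) ``mean`` is the point HR (reproduced as the distribution's
    median, log-mean = ln HR) and ``se`` is the standard deviation on the
    log scale.
    """

    target: str
    family: str
    mean: float
    se: float


class LifeTable:
    """Annual background death probability by integer age and sex.

    Lookup clamps to the last tabulated age; a table is considered to
    cover all older ages when its final row has ``q_annual = 1`` (a
    terminal age beyond which no one survives).
    """

    def __init__(self, ages, q_female, q_male):
        self.ages = np.asarray(ages, dtype=int)
        self.q_female = np.asarray(q_female, dtype=float)
        self.q_male = np.asarray(q_male, dtype=float)
        if not (len(self.ages) == len(self.q_female) == len(self.q_male)):
            raise ValueError("life table columns have unequal length")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life table ages must be consecutive integers")

    @classmethod
    def from_rows(cls, rows):
        """Build from (age, sex, q_annual) records with sex in {female, male}."""
        by_sex = {"female": {}, "male": {}}
        for age, sex, q in rows:
            by_sex[sex][int(age)] = float(q)
        ages = sorted(by_sex["female"])
        return cls(ages, [by_sex["female"][a] for a in ages], [by_sex["male"][a] for a in ages])

    @classmethod
    def from_csv(cls, path):
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = [(r["age"], r["sex"], r["q_annual"]) for r in reader]
        return cls.from_rows(rows)

    def to_rows(self):
        out = []
        for sex, col in (("female", self.q_female), ("male", self.q_male)):
            out.extend((int(a), sex, float(q)) for a, q in zip(self.ages, col))
        return out

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "sex", "q_annual"])
            w.writerows(self.to_rows())

    def _clamp(self, age: float) -> int:
        idx = int(math.floor(age)) - int(self.ages[0])
        return min(max(idx, 0), len(self.ages) - 1)

    def q(self, age: float, sex: str) -> float:
        col = self.q_female if sex == "female" else self.q_male
        return float(col[self._clamp(age)])

    def mixed_rate_annual(self, age: float, sex_mix: float) -> float:
        """Sex-averaged annual mortality hazard: female and male hazards
        mixed with weights ``sex_mix`` / ``1 - sex_mix``."""
        i = self._clamp(age)
        qf, qm = float(self.q_female[i]), float(self.q_male[i])
        rf = math.inf if qf >= 1 else -math.log1p(-qf)
        rm = math.inf if qm >= 1 else -math.log1p(-qm)
        return sex_mix * rf + (1.0 - sex_mix) * rm

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @property
    def terminal(self) -> bool:
        return bool(self.q_female[-1] >= 1.0 and self.q_male[-1] >= 1.0)

    def __eq__(self, other):
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.q_female, other.q_female)
            and np.array_equal(self.q_male, other.q_male)
        )


@dataclass
class ParameterSet:
    """Complete model specification.  State order encodes severity
    (least severe first, the absorbing Dead state last); the first state
    is the cohort's start state."""

    states: list
    transitions: list
    treatments: list
    life_table: LifeTable
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    psa_distributions: list = field(default_factory=list)
    tunnels: list = field(default_factory=list)

    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def state_index(self, name: str) -> int:
        for i, s in enumerate(self.states):
            if s.name == name:
                return i
        raise KeyError(name)

    def treatment(self, name: str) -> TreatmentDefinition:
        for t in self.treatments:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def state_names(self):
        return [s.name for s in self.states]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# validation

_VALID_FAMILIES = {"beta", "gamma", "lognormal", "normal"}
_VALID_TIMESCALES = {"annual", "per_cycle"}


def validate(ps: ParameterSet) -> list:
    """Check every structural invariant; return a list of human-readable
    violation strings (empty list means the set is valid).  Violations are
    returned rather than raised so a configuration can be fully linted in
    one pass."""
    v = []
    names = ps.state_names
    if len(set(names)) != len(names):
        v.append("state names are not unique")
    index = {n: i for i, n in enumerate(names)}

    absorbing = [s for s in ps.states if s.is_absorbing]
    if len(absorbing) != 1:
        v.append(f"expected exactly one absorbing state, found {len(absorbing)}")
    else:
        dead = absorbing[0]
        if dead.utility != 0 or dead.cost_healthcare != 0 or dead.cost_productivity != 0:
            v.append(f"absorbing state '{dead.name}' must have zero utility and costs")
        if dead.name != names[-1]:
            v.append(f"absorbing state '{dead.name}' must be last in the severity order")

    for s in ps.states:
        if not (0.0 <= s.utility <= 1.0):
            v.append(f"state '{s.name}': utility {s.utility} outside [0, 1]")
        if s.cost_healthcare < 0 or s.cost_productivity < 0:
            v.append(f"state '{s.name}': negative cost")
        if not (0.0 <= s.excess_mortality_annual < 1.0):
            v.append(
                f"state '{s.name}': excess_mortality_annual "
                f"{s.excess_mortality_annual} outside [0, 1)"
            )

    cpy = ps.settings.cycles_per_year
    outgoing = {n: 0.0 for n in names}
    for t in ps.transitions:
        label = f"transition {t.from_state}->{t.to_state}"
        if t.from_state not in index or t.to_state not in index:
            v.append(f"{label}: endpoint names an unknown state")
            continue
        if t.from_state == t.to_state:
            v.append(f"{label}: self-transitions are implicit (residual), not specified")
        if not (0.0 <= t.probability <= 1.0):
            v.append(f"{label}: probability {t.probability} outside [0, 1]")
        if t.timescale not in _VALID_TIMESCALES:
            v.append(f"{label}: unknown timescale '{t.timescale}'")
        if ps.state(t.from_state).is_absorbing if t.from_state in index else False:
            v.append(f"{label}: leaves the absorbing state")
        if index[t.to_state] < index[t.from_state]:
            v.append(f"{label}: remission to a less-severe state is not allowed")
        if t.timescale == "annual" and 0 <= t.probability <= 1:
            p_cycle = 1.0 - (1.0 - t.probability) ** (1.0 / cpy)
        else:
            p_cycle = t.probability
        outgoing[t.from_state] += p_cycle
    for n, total in outgoing.items():
        if total > 1.0 + 1e-12:
            v.append(f"state '{n}': outgoing per-cycle probabilities sum to {total:.6f} > 1")

    for tn in ps.tunnels:
        if tn.state not in index or tn.successor not in index:
            v.append(f"tunnel {tn.state}->{tn.successor}: endpoint names an unknown state")
        elif index[tn.successor] <= index[tn.state]:
            v.append(f"tunnel {tn.state}->{tn.successor}: successor must be more severe")
        if tn.cycles < 1:
            v.append(f"tunnel {tn.state}: cycles must be >= 1")

    tnames = [t.name for t in ps.treatments]
    if len(set(tnames)) != len(tnames):
        v.append("treatment names are not unique")
    for tr in ps.treatments:
        if tr.one_off_cost < 0 or tr.per_cycle_cost < 0:
            v.append(f"treatment '{tr.name}': negative cost")
        for (a, b), hr in tr.hazard_ratios.items():
            if hr < 0:
                v.append(f"treatment '{tr.name}': hazard ratio for {a}->{b} is negative")
            if a not in index or b not in index:
                v.append(f"treatment '{tr.name}': hazard ratio names unknown state {a}->{b}")

    st = ps.settings
    if not (0.0 <= st.discount_rate_annual <= 0.1):
        v.append(f"settings: discount_rate_annual {st.discount_rate_annual} outside [0, 0.1]")
    if st.horizon_years <= 0:
        v.append("settings: horizon must be positive")
    if st.wtp < 0:
        v.append("settings: wtp must be non-negative")
    if not (0.0 <= st.sex_mix <= 1.0):
        v.append(f"settings: sex_mix {st.sex_mix} outside [0, 1]")

    lt = ps.life_table
    end_age = st.start_age + st.horizon_years
    if lt.ages[0] > st.start_age:
        v.append(f"life table starts at age {lt.ages[0]}, after start_age {st.start_age}")
    if lt.max_age < end_age and not lt.terminal:
        v.append(
            f"life table ends at age {lt.max_age} (< start_age + horizon = {end_age:g}) "
            "without a terminal q_annual = 1 row"
        )

    for d in ps.psa_distributions:
        if d.family not in _VALID_FAMILIES:
            v.append(f"distribution for '{d.target}': unknown family '{d.family}'")
        if d.se < 0:
            v.append(f"distribution for '{d.target}': negative se")
        kind = d.target.split(":", 1)[0]
        is_prob = (
            d.target.endswith(".probability")
            or d.target.endswith(".utility")
            or d.target.endswith(".excess_mortality_annual")
        )
        is_cost = "cost" in d.target
        is_hr = ".hr:" in d.target
        if is_prob and d.family not in ("beta", "normal"):
            v.append(f"distribution for '{d.target}': probabilities/utilities need beta")
        if is_cost and d.family not in ("gamma", "normal"):
            v.append(f"distribution for '{d.target}': costs need gamma")
        if is_hr and d.family != "lognormal":
            v.append(f"distribution for '{d.target}': hazard ratios need lognormal")
        if kind not in ("state", "transition", "treatment"):
            v.append(f"distribution for '{d.target}': unknown target kind '{kind}'")

    return v


# ---------------------------------------------------------------------------
# packaged DKD model

#: scenario label -> settings/cost-column overrides
DKD_SCENARIOS = {
    "base": dict(start_age=71.0, sex_mix=0.5, country="base", discount=0.03),
    "age40": dict(start_age=40.0, sex_mix=0.5, country="base", discount=0.03),
    "female": dict(start_age=71.0, sex_mix=1.0, country="base", discount=0.03),
    "male": dict(start_age=71.0, sex_mix=0.0, country="base", discount=0.03),
    "uk": dict(start_age=71.0, sex_mix=0.5, country="uk", discount=0.035),
    "ireland": dict(start_age=71.0, sex_mix=0.5, country="ireland", discount=0.04),
    "italy": dict(start_age=71.0, sex_mix=0.5, country="italy", discount=0.03),
}

_DKD_PSA_REL_SE = 0.15  # relative SE used for the fixture's default PSA specs


def _read_packaged_csv(name: str) -> list:
    ref = resources.files("dkdcea.data").joinpath(name)
    with ref.open("r", newline="") as fh:
        return list(csv.DictReader(fh))


def table1_totals() -> list:
    """Published per-arm totals (cost in USD, QALYs) for each reported
    scenario, as packaged reference data.  Returns a list of dicts with
    keys scenario, strategy, cost_usd, qalys."""
    rows = _read_packaged_csv("table1_totals.csv")
    return [
        dict(
            scenario=r["scenario"],
            strategy=r["strategy"],
            cost_usd=float(r["cost_usd"]),
            qalys=float(r["qalys"]),
        )
        for r in rows
    ]


def _dkd_psa_specs(states, transitions, treatments) -> list:
    """Default moment-matched uncertainty specs for the DKD fixture:
    beta for utilities and transition probabilities, gamma for costs,
    lognormal for hazard ratios."""
    specs = []
    rel = _DKD_PSA_REL_SE
    for s in states:
        if s.is_absorbing:
            continue
        specs.append(
            DistributionSpec(f"state:{s.name}.utility", "beta", s.utility, rel * s.utility)
        )
        specs.append(
            DistributionSpec(
                f"state:{s.name}.cost_healthcare", "gamma", s.cost_healthcare,
                rel * s.cost_healthcare,
            )
        )
        if s.excess_mortality_annual > 0:
            specs.append(
                DistributionSpec(
                    f"state:{s.name}.excess_mortality_annual", "beta",
                    s.excess_mortality_annual, rel * s.excess_mortality_annual,
                )
            )
    for t in transitions:
        specs.append(
            DistributionSpec(
                f"transition:{t.from_state}->{t.to_state}.probability", "beta",
                t.probability, rel * t.probability,
            )
        )
    for tr in treatments:
        for (a, b), hr in tr.hazard_ratios.items():
            if hr > 0:
                specs.append(
                    DistributionSpec(f"treatment:{tr.name}.hr:{a}->{b}", "lognormal", hr, 0.15)
                )
    return specs


def dkd_fixture(scenario: str = "base") -> ParameterSet:
    """The packaged diabetic-kidney-disease model.

    States: CKD (stages 3–4 combined), ESRD1 (dialysis), ESRD2 (kidney
    transplant, first year), ESRD2.2 (transplant, subsequent years), Dead.
    Treatments: MSC (one-off cell therapy, hazard ratio on progression to
    renal replacement) and SGLT2i (monthly drug cost while in CKD, hazard
    ratios on progression and death).

    ``scenario`` selects the base case (age 71, sex-averaged, pooled
    country costs, 3% discount) or one of the reported variants:
    ``age40``, ``male``, ``female``, ``uk`` (3.5% discount), ``ireland``
    (4%), ``italy`` (3%), each with its own cost column.

    Input values carry a provenance column in the packaged CSVs: values
    printed in the source study body are marked accordingly; the
    remainder are synthetic placeholders with the correct structure, so
    substituting measured values is a data edit, not a code edit.
    """
    if scenario not in DKD_SCENARIOS:
        raise KeyError(
            f"unknown scenario '{scenario}'; expected one of {sorted(DKD_SCENARIOS)}"
        )
    sc = DKD_SCENARIOS[scenario]
    country = sc["country"]

    cost_rows = _read_packaged_csv("dkd_costs.csv")
    costs = {
        r["state"]: float(r[f"cost_healthcare_annual_{country}"]) for r in cost_rows
    }

    states = []
    for r in _read_packaged_csv("dkd_states.csv"):
        name = r["name"]
        states.append(
            HealthState(
                name=name,
                utility=float(r["utility"]),
                cost_healthcare=costs.get(name, 0.0) / 12.0,
                cost_productivity=float(r["cost_productivity_annual"]) / 12.0,
                excess_mortality_annual=float(r["excess_mortality_annual"]),
                is_absorbing=r["is_absorbing"] == "1",
                tags=frozenset(t for t in r["tags"].split("|") if t),
            )
        )

    transitions = [
        TransitionSpec(r["from_state"], r["to_state"], float(r["probability_annual"]), "annual")
        for r in _read_packaged_csv("dkd_transitions.csv")
    ]

    hr_rows = _read_packaged_csv("dkd_hazard_ratios.csv")
    treatments = []
    for r in _read_packaged_csv("dkd_treatments.csv"):
        if r["country"] != country:
            continue
        name = r["treatment"]
        hrs = {
            (h["from_state"], h["to_state"]): float(h["hr"])
            for h in hr_rows
            if h["treatment"] == name
        }
        treatments.append(
            TreatmentDefinition(
                name=name,
                one_off_cost=float(r["one_off_cost"]),
                per_cycle_cost=float(r["per_cycle_cost"]),
                cost_state_tags=frozenset(t for t in r["cost_state_tags"].split("|") if t),
                hazard_ratios=hrs,
            )
        )

    life_table = LifeTable.from_rows(
        (r["age"], r["sex"], r["q_annual"]) for r in _read_packaged_csv("dkd_life_table.csv")
    )

    settings = AnalysisSettings(
        cycle_length_months=1,
        horizon_years=100.0,
        discount_rate_annual=sc["discount"],
        wtp=47_000.0,
        start_age=sc["start_age"],
        sex_mix=sc["sex_mix"],
        retirement_age=65.0,
        seed=0,
    )

    ps = ParameterSet(
        states=states,
        transitions=transitions,
        treatments=treatments,
        life_table=life_table,
        settings=settings,
        psa_distributions=_dkd_psa_specs(states, transitions, treatments),
        tunnels=[TunnelSpec("ESRD2", "ESRD2.2", cycles=12)],
    )
    return ps


def with_settings(ps: ParameterSet, **changes) -> ParameterSet:
    """Return a copy of ``ps`` with the given AnalysisSettings fields
    replaced."""
    out = ps.copy()
    out.settings = replace(out.settings, **changes)
    return out
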