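"""Probability/rate algebra and cycle-indexed transition matrices.

All conversions between probabilities and hazards go through the
exponential (constant-rate-within-interval) relationship
``p = 1 - exp(-r t)``.  Hazard ratios act multiplicatively on the rate
scale, so treatment effects commute with timescale conversion and remain
coherent at HR = 0 (transition eliminated) and HR > 1.

:func:`build_transition_model` assembles, for every cycle, a
row-stochastic matrix over an internally *expanded* state space: states
with a deterministic tunnel handover (e.g. transplant year 1 → subsequent
years after 12 cycles) are expanded into per-cycle-since-entry sub-states,
which are collapsed back to the reported states for output.  Background
mortality is injected per cycle from the life table at the cohort's
current age (``start_age + floor(cycle/12)``), sex-mixed on the rate
scale, and combined with state-specific excess mortality as independent
competing hazards.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet, TreatmentDefinition, validate

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "annual_prob_to_cycle_prob",
    "apply_hazard_ratio",
    "combine_mortality",
    "TransitionModel",
    "build_transition_model",
]

MAX_CYCLES = 1200  # horizon cap: 100 years of monthly cycles


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Hazard rate over period ``t`` equivalent to probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 1.0:
        return math.inf
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Probability over period ``t`` equivalent to hazard rate ``r``."""
    if r < 0:
        raise ValueError(f"rate {r} must be non-negative")
    return -math.expm1(-r * t)


def annual_prob_to_cycle_prob(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to the per-cycle probability with the
    same constant hazard: ``1 - (1 - p)^(1/cycles_per_year)``."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"probability {p_annual} outside [0, 1]")
    return -math.expm1(math.log1p(-p_annual) / cycles_per_year) if p_annual < 1.0 else 1.0


def apply_hazard_ratio(p_cycle: float, hr: float) -> float:
    """Scale a per-cycle probability by a hazard ratio on the rate scale:
    ``1 - (1 - p)^hr``.  HR = 1 is the identity; HR = 0 eliminates the
    transition."""
    if hr < 0:
        raise ValueError(f"hazard ratio {hr} must be non-negative")
    if not 0.0 <= p_cycle <= 1.0:
        raise ValueError(f"probability {p_cycle} outside [0, 1]")
    if p_cycle == 1.0:
        if hr == 1.0:
            return 1.0
        raise ValueError("cannot apply a hazard ratio to a certain event (infinite rate)")
    return -math.expm1(hr * math.log1p(-p_cycle))


def combine_mortality(
    excess_annual: float, background_annual: float, cycles_per_year: int
) -> float:
    """Per-cycle death probability from independent competing hazards:
    annual rates add, then convert to one cycle."""
    for q in (excess_annual, background_annual):
        if not 0.0 <= q < 1.0:
            raise ValueError(f"annual probability {q} outside [0, 1)")
    r = -math.log1p(-excess_annual) - math.log1p(-background_annual)
    return -math.expm1(-r / cycles_per_year)


class TransitionModel:
    """Cycle-indexed row-stochastic transition matrices.

    Matrices live on the expanded (tunnel sub-state) space; ``collapse``
    maps expanded occupancy vectors back to the reported states.
    Matrices depend on cycle only through the cohort's integer age, so
    one matrix is built and cached per model year.
    """

    def __init__(self, ps, treatment, expanded_names, expanded_to_reported, n_cycles):
        self._ps = ps
        self._treatment = treatment
        self.expanded_names = list(expanded_names)
        self.expanded_to_reported = np.asarray(expanded_to_reported, dtype=int)
        self.state_names = ps.state_names
        self.n_states = len(self.state_names)
        self.n_expanded = len(self.expanded_names)
        self.n_cycles = int(n_cycles)
        self._year_cache: dict = {}
        # 0/1 aggregation matrix: expanded occupancy -> reported occupancy
        self.collapse = np.zeros((self.n_expanded, self.n_states))
        self.collapse[np.arange(self.n_expanded), self.expanded_to_reported] = 1.0

    # -- per-expanded-state attribute vectors (reported-state values) ------
    def attribute_vector(self, getter) -> np.ndarray:
        vals = np.array([getter(s) for s in self._ps.states], dtype=float)
        return vals[self.expanded_to_reported]

    def matrix_for_cycle(self, cycle: int) -> np.ndarray:
        year = cycle // self._ps.settings.cycles_per_year
        m = self._year_cache.get(year)
        if m is None:
            m = _build_year_matrix(self._ps, self._treatment, self, year)
            self._year_cache[year] = m
        return m

    def collapse_occupancy(self, occ_expanded: np.ndarray) -> np.ndarray:
        return occ_expanded @ self.collapse

    def start_vector(self) -> np.ndarray:
        v = np.zeros(self.n_expanded)
        v[0] = 1.0
        return v


def _expand_states(ps: ParameterSet):
    """Expanded state list: each tunnel state becomes ``cycles``
    sub-states; entry into the state targets sub-state 1."""
    tunnels = {t.state: t for t in ps.tunnels}
    expanded_names, mapping, entry_index = [], [], {}
    for i, s in enumerate(ps.states):
        entry_index[s.name] = len(expanded_names)
        if s.name in tunnels:
            for k in range(tunnels[s.name].cycles):
                expanded_names.append(f"{s.name}#{k + 1}")
                mapping.append(i)
        else:
            expanded_names.append(s.name)
            mapping.append(i)
    return expanded_names, mapping, entry_index, tunnels


def build_transition_model(
    ps: ParameterSet, treatment: TreatmentDefinition | None = None
) -> TransitionModel:
    """Assemble the cycle-indexed transition model for one strategy.

    Per cycle: annual transition specs are converted to per-cycle
    probabilities, treatment hazard ratios applied on the rate scale,
    background mortality (life table at current cohort age, sex-mixed)
    combined with state excess mortality into the death transition, and
    the residual probability assigned to the self-loop (or, for tunnel
    sub-states, to advancing along the tunnel).
    """
    problems = validate(ps)
    if problems:
        raise ValueError("invalid ParameterSet: " + "; ".join(problems))
    expanded_names, mapping, entry_index, tunnels = _expand_states(ps)
    n_cycles = min(
        int(round(ps.settings.horizon_years * ps.settings.cycles_per_year)), MAX_CYCLES
    )
    tm = TransitionModel(ps, treatment, expanded_names, mapping, n_cycles)
    tm._entry_index = entry_index
    tm._tunnels = tunnels
    return tm


def _build_year_matrix(ps, treatment, tm, year) -> np.ndarray:
    cpy = ps.settings.cycles_per_year
    age = ps.settings.start_age + year
    r_bg_annual = ps.life_table.mixed_rate_annual(age, ps.settings.sex_mix)
    q_bg_annual = -math.expm1(-r_bg_annual) if math.isfinite(r_bg_annual) else 1.0

    hrs = treatment.hazard_ratios if treatment is not None else {}
    dead_name = ps.states[-1].name

    # per-cycle disease transition probabilities by (from, to) reported name
    p_cycle: dict = {}
    for t in ps.transitions:
        p = (
            annual_prob_to_cycle_prob(t.probability, cpy)
            if t.timescale == "annual"
            else t.probability
        )
        hr = hrs.get((t.from_state, t.to_state))
        if hr is not None:
            p = apply_hazard_ratio(p, hr)
        p_cycle[(t.from_state, t.to_state)] = p_cycle.get((t.from_state, t.to_state), 0.0) + p

    n = tm.n_expanded
    M = np.zeros((n, n))
    dead_idx = tm._entry_index[dead_name]

    for e, name in enumerate(tm.expanded_names):
        base = name.split("#", 1)[0]
        state = ps.state(base)
        if state.is_absorbing:
            M[e, e] = 1.0
            continue

        # past the life table's terminal age no one survives: the entire
        # row moves to the absorbing state and disease transitions are moot
        if q_bg_annual >= 1.0:
            M[e, dead_idx] = 1.0
            continue

        # death: background + excess on the rate scale, optional mortality HR
        p_death = combine_mortality(state.excess_mortality_annual, q_bg_annual, cpy)
        hr_death = hrs.get((base, dead_name))
        if hr_death is not None and p_death < 1.0:
            p_death = apply_hazard_ratio(p_death, hr_death)
        # explicit (state -> Dead) transition specs add to the same cell
        p_death_extra = p_cycle.get((base, dead_name), 0.0)

        row_sum = p_death + p_death_extra
        M[e, dead_idx] = row_sum
        for (a, b), p in p_cycle.items():
            if a != base or b == dead_name:
                continue
            M[e, tm._entry_index[b]] += p
            row_sum += p
        if row_sum > 1.0 + 1e-12:
            raise ValueError(
                f"state '{name}', year {year}: outgoing probabilities sum to "
                f"{row_sum:.6f} > 1 before residual assignment"
            )
        residual = max(1.0 - row_sum, 0.0)

        if base in tm._tunnels:
            k = int(name.split("#", 1)[1])
            tun = tm._tunnels[base]
            if k < tun.cycles:
                M[e, e + 1] += residual  # advance along the tunnel
            else:
                M[e, tm._entry_index[tun.successor]] += residual  # forced handover
        else:
            M[e, e] += residual

    # row-stochasticity is exact by construction up to rounding
    np.clip(M, 0.0, 1.0, out=M)
    M /= M.sum(axis=1, keepdims=True)
    return M
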