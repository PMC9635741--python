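"""Probabilistic sensitivity analysis.

Each iteration draws one parameter set from the moment-matched
uncertainty distributions (beta for probabilities and utilities, gamma
for costs, lognormal for hazard ratios) and evaluates *every* strategy on
that common draw — arms share parameter uncertainty and differ only by
treatment effect and cost, which is what makes per-iteration net-benefit
comparisons meaningful.  Results feed cost-effectiveness acceptability
curves (CEACs): the probability, across draws, that each strategy has the
maximal net monetary benefit at a given willingness-to-pay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cea import nmb
from .engine import run_cohort
from .parameters import DistributionSpec, ParameterSet

__all__ = [
    "beta_params",
    "gamma_params",
    "draw_value",
    "sample_parameters",
    "PSAResult",
    "run_psa",
    "CEACCurve",
    "ceac",
    "prob_cost_effective",
    "DEFAULT_WTP_GRID",
]

#: default CEAC threshold grid: $0 to $150,000 per QALY in $1,000 steps
DEFAULT_WTP_GRID = np.arange(0, 150_001, 1_000, dtype=float)


# ---------------------------------------------------------------------------
# moment matching

def beta_params(mean: float, se: float) -> tuple[float, float]:
    """(α, β) of the beta distribution with the given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean {mean} must be in (0, 1)")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(f"beta se {se} too large for mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params(mean: float, se: float) -> tuple[float, float]:
    """(shape, scale) of the gamma distribution with the given mean and SE."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma moment matching needs positive mean and se")
    shape = (mean / se) ** 2
    return shape, se * se / mean


def draw_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from a DistributionSpec.  Zero SE collapses to the point
    value, so degenerate specs make the PSA deterministic."""
    if spec.se == 0:
        return spec.mean
    if spec.family == "beta":
        a, b = beta_params(spec.mean, spec.se)
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape, scale = gamma_params(spec.mean, spec.se)
        return float(rng.gamma(shape, scale))
    if spec.family == "lognormal":
        # median reproduces the point hazard ratio; se is the log-scale SD
        return float(rng.lognormal(np.log(spec.mean), spec.se))
    if spec.family == "normal":
        return float(rng.normal(spec.mean, spec.se))
    raise ValueError(f"unknown family '{spec.family}'")


# ---------------------------------------------------------------------------
# target-path resolution

_STATE_RE = re.compile(r"^state:(?P<name>.+)\.(?P<field>\w+)$")
_TRANS_RE = re.compile(r"^transition:(?P<from>.+)->(?P<to>.+)\.probability$")
_TREAT_HR_RE = re.compile(r"^treatment:(?P<name>.+)\.hr:(?P<from>.+)->(?P<to>.+)$")
_TREAT_RE = re.compile(r"^treatment:(?P<name>.+)\.(?P<field>one_off_cost|per_cycle_cost)$")


def _assign(ps: ParameterSet, target: str, value: float) -> None:
    m = _STATE_RE.match(target)
    if m and ":" not in m.group("name"):
        i = ps.state_index(m.group("name"))
        ps.states[i] = replace(ps.states[i], **{m.group("field"): value})
        return
    m = _TRANS_RE.match(target)
    if m:
        for i, t in enumerate(ps.transitions):
            if t.from_state == m.group("from") and t.to_state == m.group("to"):
                ps.transitions[i] = replace(t, probability=value)
                return
        raise KeyError(f"no transition matches '{target}'")
    m = _TREAT_HR_RE.match(target)
    if m:
        for i, tr in enumerate(ps.treatments):
            if tr.name == m.group("name"):
                hrs = dict(tr.hazard_ratios)
                key = (m.group("from"), m.group("to"))
                if key not in hrs:
                    raise KeyError(f"treatment '{tr.name}' has no HR for {key}")
                hrs[key] = value
                ps.treatments[i] = replace(tr, hazard_ratios=hrs)
                return
        raise KeyError(f"no treatment matches '{target}'")
    m = _TREAT_RE.match(target)
    if m:
        for i, tr in enumerate(ps.treatments):
            if tr.name == m.group("name"):
                ps.treatments[i] = replace(tr, **{m.group("field"): value})
                return
        raise KeyError(f"no treatment matches '{target}'")
    raise KeyError(f"unparseable parameter path '{target}'")


def sample_parameters(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Deep variant of ``ps`` with each distribution target replaced by
    one independent draw; parameters without a spec are untouched."""
    out = ps.copy()
    for spec in ps.psa_distributions:
        _assign(out, spec.target, draw_value(spec, rng))
    return out


# ---------------------------------------------------------------------------
# PSA driver

@dataclass
class PSAResult:
    """Per-iteration (cost, QALY) pairs per strategy."""

    arm_names: list
    costs: np.ndarray  # (n_iterations, n_arms)
    qalys: np.ndarray  # (n_iterations, n_arms)
    seed: int
    wtp_grid: np.ndarray = field(default_factory=lambda: DEFAULT_WTP_GRID.copy())

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "arm": self.arm_names * n,
                "cost": self.costs.ravel(),
                "qaly": self.qalys.ravel(),
            }
        )


def run_psa(
    ps: ParameterSet,
    arms: list,
    n_iterations: int,
    seed: int,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: ``arms`` is a list of TreatmentDefinition-or-None
    (None = usual care).  One parameter draw per iteration is shared by
    all arms; arm evaluation uses the deterministic cohort engine
    (second-order uncertainty only).  Reproducible for a given seed."""
    from .engine import arm_name

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    names = [arm_name(a) for a in arms]
    costs = np.empty((n_iterations, len(arms)))
    qalys = np.empty((n_iterations, len(arms)))
    for it in range(n_iterations):
        try:
            drawn = sample_parameters(ps, rng)
            for j, arm in enumerate(arms):
                # treatment definitions may themselves be sampled: evaluate
                # the drawn set's treatment of the same name where present
                tr = None
                if arm is not None:
                    try:
                        tr = drawn.treatment(arm.name)
                    except KeyError:
                        tr = arm
                res = run_cohort(drawn, tr)
                costs[it, j] = res.total_cost
                qalys[it, j] = res.total_qaly
        except Exception as exc:  # attach the iteration index for debugging
            raise RuntimeError(f"PSA iteration {it} failed: {exc}") from exc
    grid = DEFAULT_WTP_GRID.copy() if wtp_grid is None else np.asarray(wtp_grid, float)
    return PSAResult(names, costs, qalys, seed, grid)


# ---------------------------------------------------------------------------
# CEAC

@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective (maximal NMB) across a
    willingness-to-pay grid; columns sum to 1 (NMB ties split equally)."""

    arm_names: list
    wtp_grid: np.ndarray
    prob_ce: np.ndarray  # (n_arms, n_wtp)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, arm in enumerate(self.arm_names):
            for j, w in enumerate(self.wtp_grid):
                recs.append(dict(wtp=float(w), arm=arm, probability=self.prob_ce[i, j]))
        return pd.DataFrame.from_records(recs)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    grid = psa.wtp_grid if wtp_grid is None else np.asarray(wtp_grid, float)
    n, k = psa.costs.shape
    prob = np.zeros((k, len(grid)))
    for j, w in enumerate(grid):
        net = nmb(psa.costs, psa.qalys, w)  # (n, k), vectorised
        best = net.max(axis=1, keepdims=True)
        winners = net == best
        prob[:, j] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n
    return CEACCurve(list(psa.arm_names), grid, prob)


def prob_cost_effective(psa: PSAResult, wtp: float) -> dict:
    """Probability each arm is cost-effective at a single threshold."""
    curve = ceac(psa, np.array([wtp], dtype=float))
    return {arm: float(curve.prob_ce[i, 0]) for i, arm in enumerate(curve.arm_names)}
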