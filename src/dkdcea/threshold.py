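"""Scenario re-evaluation and two-way cost × effect threshold analysis.

``two_way_threshold`` maps out, over a grid of hazard ratios (treatment
effect on progression to renal replacement) and one-off treatment costs,
which strategy has the maximal net monetary benefit at a fixed
willingness-to-pay — the decision-surface view used to locate the price
an emerging therapy could command at a given effectiveness.
``extract_boundary`` pulls out the indifference frontier: for each hazard
ratio, the dose cost at which the therapy's net benefit equals the best
alternative's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cea import classify_dominance, comparison_table, nmb
from .engine import arm_name, run_cohort
from .parameters import ParameterSet, dkd_fixture

__all__ = [
    "run_scenarios",
    "ThresholdGrid",
    "two_way_threshold",
    "extract_boundary",
    "DEFAULT_HR_GRID",
    "DEFAULT_COST_GRID",
]

DEFAULT_HR_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)
DEFAULT_COST_GRID = np.arange(0.0, 80_001.0, 2_500.0)


def evaluate_arms(ps: ParameterSet, include_untreated: bool = True) -> list:
    """Run the cohort engine for usual care plus every treatment in
    ``ps``; returns a list of ArmResult."""
    arms = ([None] if include_untreated else []) + list(ps.treatments)
    return [run_cohort(ps, a) for a in arms]


def run_scenarios(scenario_labels, wtp: float | None = None) -> dict:
    """Fully re-evaluate all strategies of the packaged DKD model for
    each scenario label; returns ``{label: comparison DataFrame}``."""
    out = {}
    for label in scenario_labels:
        ps = dkd_fixture(label)
        results = evaluate_arms(ps)
        rows = classify_dominance(results, ps.settings.wtp if wtp is None else wtp)
        out[label] = comparison_table(rows)
    return out


@dataclass
class ThresholdGrid:
    """Winner map and net-benefit margin over (HR, one-off cost)."""

    treatment: str
    hr_values: np.ndarray
    cost_values: np.ndarray
    winner: np.ndarray  # (n_hr, n_cost) array of strategy labels
    inmb: np.ndarray  # treatment NMB minus best-alternative NMB
    wtp: float


def two_way_threshold(
    base: ParameterSet,
    hr_grid: np.ndarray | None = None,
    cost_grid: np.ndarray | None = None,
    wtp: float | None = None,
    treatment_name: str = "MSC",
) -> ThresholdGrid:
    """Vary one treatment's effect and one-off cost simultaneously.

    For each grid HR the treatment's hazard ratios on every transition
    from a CKD-tagged state to an ESRD-tagged state are set to that value
    (mortality HRs, if any, are left untouched); for each grid cost its
    one-off cost is set to that value.  All other arms are evaluated once
    (they do not depend on the grid), and because the one-off cost enters
    the total additively (booked undiscounted at cycle 0) a single cohort
    run per HR suffices.
    """
    hr_grid = DEFAULT_HR_GRID if hr_grid is None else np.asarray(hr_grid, float)
    cost_grid = DEFAULT_COST_GRID if cost_grid is None else np.asarray(cost_grid, float)
    wtp = base.settings.wtp if wtp is None else float(wtp)
    target = base.treatment(treatment_name)

    progression_keys = _ckd_to_esrd_pairs(base)
    if not progression_keys:
        raise ValueError("no CKD->ESRD transitions found to vary")

    others = [t for t in base.treatments if t.name != treatment_name]
    other_results = [run_cohort(base, a) for a in [None] + others]
    other_names = [arm_name(a) for a in [None] + others]
    other_nmb = np.array([nmb(r.total_cost, r.total_qaly, wtp) for r in other_results])

    n_hr, n_cost = len(hr_grid), len(cost_grid)
    winner = np.empty((n_hr, n_cost), dtype=object)
    margin = np.empty((n_hr, n_cost))
    best_other = float(other_nmb.max())
    best_other_name = other_names[int(other_nmb.argmax())]

    for i, hr in enumerate(hr_grid):
        hrs = dict(target.hazard_ratios)
        for key in progression_keys:
            hrs[key] = float(hr)
        varied = replace(target, hazard_ratios=hrs, one_off_cost=0.0)
        res = run_cohort(base, varied)
        nmb0 = nmb(res.total_cost, res.total_qaly, wtp)
        for j, cost in enumerate(cost_grid):
            m = (nmb0 - cost) - best_other
            margin[i, j] = m
            winner[i, j] = treatment_name if m > 0 else best_other_name

    return ThresholdGrid(treatment_name, hr_grid, cost_grid, winner, margin, wtp)


def _ckd_to_esrd_pairs(ps: ParameterSet):
    pairs = []
    for t in ps.transitions:
        if "CKD" in ps.state(t.from_state).tags and "ESRD" in ps.state(t.to_state).tags:
            pairs.append((t.from_state, t.to_state))
    return pairs


def extract_boundary(grid: ThresholdGrid) -> list:
    """Indifference boundary: for each HR, the one-off cost at which the
    varied treatment's net benefit crosses the best alternative's
    (linear interpolation between bracketing grid cells).

    HRs where the treatment never wins (margin ≤ 0 even at zero cost) are
    omitted; where it still wins at the top of the cost grid the boundary
    lies beyond the grid and is reported as ``inf``.  Raises on a
    non-monotone margin column (the margin must fall strictly with cost).
    """
    out = []
    for i, hr in enumerate(grid.hr_values):
        col = grid.inmb[i]
        if np.any(np.diff(col) >= 0):
            raise ValueError(
                f"net-benefit margin not strictly decreasing in cost at HR={hr}"
            )
        if col[0] <= 0:
            continue
        if col[-1] > 0:
            out.append((float(hr), math.inf))
            continue
        k = int(np.nonzero(col <= 0)[0][0])
        c0, c1 = grid.cost_values[k - 1], grid.cost_values[k]
        m0, m1 = col[k - 1], col[k]
        cost = c0 + (c1 - c0) * m0 / (m0 - m1)
        out.append((float(hr), float(cost)))
    return out
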