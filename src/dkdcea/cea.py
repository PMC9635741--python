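"""Incremental cost-effectiveness comparison of strategies.

Implements the standard decision-analytic summary measures: incremental
cost and QALYs, the ICER (ΔC/ΔE), net monetary benefit at a
willingness-to-pay threshold λ (NMB = λ·E − C, INMB = λ·ΔE − ΔC), and
dominance classification on the cost-effectiveness frontier.  All rows
are reported against the least-cost undominated strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import ArmResult

__all__ = [
    "ArmTotals",
    "ComparisonRow",
    "incremental",
    "icer",
    "inmb",
    "nmb",
    "classify_dominance",
    "comparison_table",
    "UNDOMINATED",
    "ABS_DOMINATED",
    "EXT_DOMINATED",
]

UNDOMINATED = "undominated"
ABS_DOMINATED = "abs_dominated"
EXT_DOMINATED = "ext_dominated"


@dataclass(frozen=True)
class ArmTotals:
    """Bare (cost, QALY) totals for one strategy — enough for every
    comparison in this module; use when totals come from a published
    table rather than an engine run."""

    arm_name: str
    total_cost: float
    total_qaly: float


@dataclass
class ComparisonRow:
    strategy: str
    cost: float
    qaly: float
    comparator: str | None = None
    d_cost: float | None = None
    d_qaly: float | None = None
    icer: float | None = None  # None when undefined (ΔE = 0) or no comparator
    icer_note: str = ""
    inmb_at_wtp: float | None = None
    dominance: str = UNDOMINATED


def incremental(a: ArmResult, ref: ArmResult) -> tuple[float, float]:
    """(ΔC, ΔE) of strategy ``a`` relative to ``ref``; antisymmetric."""
    return a.total_cost - ref.total_cost, a.total_qaly - ref.total_qaly


def icer(d_cost: float, d_qaly: float) -> float | None:
    """ΔC/ΔE, or ``None`` when ΔE = 0 (the ratio is undefined; the sign
    of ΔC then tells the whole story)."""
    if d_qaly == 0:
        return None
    return d_cost / d_qaly


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit λ·E − C."""
    return wtp * qaly - cost


def inmb(d_cost: float, d_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit λ·ΔE − ΔC."""
    return wtp * d_qaly - d_cost


def _abs_dominated(arms: list) -> set:
    out = set()
    for a in arms:
        for b in arms:
            if b.total_cost < a.total_cost and b.total_qaly > a.total_qaly:
                out.add(a.arm_name)
                break
    return out


def _ext_dominated(frontier: list) -> set:
    """Extended dominance on the absolutely-undominated set: walking the
    frontier sorted by cost, a strategy whose ICER against its cheaper
    neighbour exceeds the next strategy's ICER against it is dominated by
    a blend of its neighbours.  Iterates until stable."""
    out: set = set()
    arms = sorted(frontier, key=lambda a: (a.total_cost, a.total_qaly))
    changed = True
    while changed and len(arms) >= 3:
        changed = False
        for i in range(1, len(arms) - 1):
            lo, mid, hi = arms[i - 1], arms[i], arms[i + 1]
            icer_lo = icer(*incremental(mid, lo))
            icer_hi = icer(*incremental(hi, mid))
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                out.add(mid.arm_name)
                arms.pop(i)
                changed = True
                break
    return out


def classify_dominance(arms: list, wtp: float) -> dict:
    """Classify each strategy (absolute / extended dominance) and report
    every row against the least-cost undominated strategy.

    Absolute dominance requires strictly higher cost *and* strictly fewer
    QALYs than some alternative; strategies tied on both are all kept
    undominated.  Returns ``{strategy: ComparisonRow}``.
    """
    if len(arms) < 2:
        raise ValueError("need at least two strategies to compare")
    absd = _abs_dominated(arms)
    frontier = [a for a in arms if a.arm_name not in absd]
    extd = _ext_dominated(frontier)
    undominated = [a for a in frontier if a.arm_name not in extd]
    comparator = min(undominated, key=lambda a: (a.total_cost, -a.total_qaly))

    rows = {}
    for a in arms:
        dom = (
            ABS_DOMINATED if a.arm_name in absd
            else EXT_DOMINATED if a.arm_name in extd
            else UNDOMINATED
        )
        row = ComparisonRow(a.arm_name, a.total_cost, a.total_qaly, dominance=dom)
        if a.arm_name != comparator.arm_name:
            d_cost, d_qaly = incremental(a, comparator)
            row.comparator = comparator.arm_name
            row.d_cost, row.d_qaly = d_cost, d_qaly
            row.icer = icer(d_cost, d_qaly)
            if row.icer is None:
                row.icer_note = (
                    "undefined (dQALY=0, " + ("dCost>0" if d_cost > 0 else
                    "dCost<0" if d_cost < 0 else "dCost=0") + ")"
                )
            row.inmb_at_wtp = inmb(d_cost, d_qaly, wtp)
        rows[a.arm_name] = row
    return rows


def comparison_table(rows: dict) -> pd.DataFrame:
    """Comparison rows as a tidy DataFrame (one strategy per row, the
    comparator first), with unrounded internal arithmetic — round only
    for display."""
    order = sorted(rows.values(), key=lambda r: (r.comparator is not None, r.cost))
    recs = []
    for r in order:
        recs.append(
            dict(
                strategy=r.strategy,
                cost=r.cost,
                qaly=r.qaly,
                comparison=(f"{r.strategy} vs. {r.comparator}" if r.comparator else ""),
                d_cost=r.d_cost,
                d_qaly=r.d_qaly,
                icer=r.icer if r.icer is not None else r.icer_note or None,
                inmb=r.inmb_at_wtp,
                dominance=r.dominance,
            )
        )
    return pd.DataFrame.from_records(recs)
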