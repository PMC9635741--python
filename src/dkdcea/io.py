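"""Configuration and result serialization.

A model configuration is one YAML document (states, transitions,
treatments, tunnels, settings, PSA distributions) plus a life-table CSV
(columns ``age, sex, q_annual``) referenced from it.  Writing and
re-reading a configuration reproduces the ParameterSet field-for-field.
Result writers emit plain CSV; currency is serialized as unrounded
decimals (display rounding belongs to report formatting, not storage).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os

import yaml

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

__all__ = [
    "parameter_set_to_dict",
    "parameter_set_from_dict",
    "save_config",
    "load_config",
    "config_hash",
    "write_comparison_csv",
    "write_trace_csv",
    "write_event_log_csv",
    "write_psa_csv",
    "write_ceac_csv",
    "write_threshold_csv",
    "write_boundary_csv",
    "RunLog",
]


def parameter_set_to_dict(ps: ParameterSet, life_table_ref: str | None = None) -> dict:
    doc: dict = {
        "states": [
            {
                "name": s.name,
                "utility": s.utility,
                "cost_healthcare": s.cost_healthcare,
                "cost_productivity": s.cost_productivity,
                "excess_mortality_annual": s.excess_mortality_annual,
                "is_absorbing": s.is_absorbing,
                "tags": sorted(s.tags),
            }
            for s in ps.states
        ],
        "transitions": [
            {
                "from": t.from_state,
                "to": t.to_state,
                "probability": t.probability,
                "timescale": t.timescale,
            }
            for t in ps.transitions
        ],
        "treatments": [
            {
                "name": t.name,
                "one_off_cost": t.one_off_cost,
                "per_cycle_cost": t.per_cycle_cost,
                "cost_state_tags": sorted(t.cost_state_tags),
                "hazard_ratios": [
                    {"from": a, "to": b, "hr": hr}
                    for (a, b), hr in sorted(t.hazard_ratios.items())
                ],
            }
            for t in ps.treatments
        ],
        "tunnels": [
            {"state": t.state, "successor": t.successor, "cycles": t.cycles}
            for t in ps.tunnels
        ],
        "settings": {
            "cycle_length_months": ps.settings.cycle_length_months,
            "horizon_years": ps.settings.horizon_years,
            "discount_rate_annual": ps.settings.discount_rate_annual,
            "wtp": ps.settings.wtp,
            "start_age": ps.settings.start_age,
            "sex_mix": ps.settings.sex_mix,
            "retirement_age": ps.settings.retirement_age,
            "seed": ps.settings.seed,
        },
        "psa_distributions": [
            {"target": d.target, "family": d.family, "mean": d.mean, "se": d.se}
            for d in ps.psa_distributions
        ],
    }
    if life_table_ref is not None:
        doc["life_table"] = life_table_ref
    return doc


def parameter_set_from_dict(doc: dict, life_table: LifeTable) -> ParameterSet:
    states = [
        HealthState(
            name=s["name"],
            utility=s["utility"],
            cost_healthcare=s.get("cost_healthcare", 0.0),
            cost_productivity=s.get("cost_productivity", 0.0),
            excess_mortality_annual=s.get("excess_mortality_annual", 0.0),
            is_absorbing=s.get("is_absorbing", False),
            tags=frozenset(s.get("tags", [])),
        )
        for s in doc["states"]
    ]
    transitions = [
        TransitionSpec(t["from"], t["to"], t["probability"], t.get("timescale", "annual"))
        for t in doc.get("transitions", [])
    ]
    treatments = [
        TreatmentDefinition(
            name=t["name"],
            one_off_cost=t.get("one_off_cost", 0.0),
            per_cycle_cost=t.get("per_cycle_cost", 0.0),
            cost_state_tags=frozenset(t.get("cost_state_tags", [])),
            hazard_ratios={
                (h["from"], h["to"]): h["hr"] for h in t.get("hazard_ratios", [])
            },
        )
        for t in doc.get("treatments", [])
    ]
    tunnels = [
        TunnelSpec(t["state"], t["successor"], t.get("cycles", 12))
        for t in doc.get("tunnels", [])
    ]
    settings = AnalysisSettings(**doc.get("settings", {}))
    dists = [
        DistributionSpec(d["target"], d["family"], d["mean"], d["se"])
        for d in doc.get("psa_distributions", [])
    ]
    return ParameterSet(states, transitions, treatments, life_table, settings, dists, tunnels)


def save_config(ps: ParameterSet, path: str, life_table_name: str | None = None) -> None:
    """Write ``ps`` as YAML at ``path`` plus a life-table CSV alongside
    (default ``<stem>_life_table.csv``), referenced from the YAML."""
    stem = os.path.splitext(os.path.basename(path))[0]
    if life_table_name is None:
        life_table_name = f"{stem}_life_table.csv"
    doc = parameter_set_to_dict(ps, life_table_ref=life_table_name)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    ps.life_table.to_csv(os.path.join(os.path.dirname(path) or ".", life_table_name))


def load_config(path: str) -> ParameterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ref = doc.get("life_table")
    if ref is None:
        raise ValueError("configuration has no 'life_table' reference")
    lt_path = ref if os.path.isabs(ref) else os.path.join(os.path.dirname(path) or ".", ref)
    return parameter_set_from_dict(doc, LifeTable.from_csv(lt_path))


def config_hash(ps: ParameterSet) -> str:
    """Stable SHA-256 of the canonical YAML form (life table included)."""
    doc = parameter_set_to_dict(ps)
    doc["_life_table_rows"] = ps.life_table.to_rows()
    text = yaml.safe_dump(doc, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# result writers

def write_comparison_csv(table, path: str) -> None:
    table.to_csv(path, index=False)


def write_trace_csv(arm_result, path: str) -> None:
    """Long-format cohort trace: cycle, state, occupancy, plus the
    per-cycle discounted accruals repeated per cycle."""
    import pandas as pd

    tr = arm_result.trace
    n = tr.n_cycles
    recs = []
    for t in range(n):
        for j, state in enumerate(tr.state_names):
            recs.append(
                dict(
                    cycle=t,
                    state=state,
                    occupancy=tr.occupancy[t, j],
                    disc_cost=tr.cost_per_cycle[t],
                    disc_qaly=tr.qaly_per_cycle[t],
                )
            )
    pd.DataFrame.from_records(recs).to_csv(path, index=False)


def write_event_log_csv(microsim_result, path: str) -> None:
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["patient_id", "state", "entry_cycle", "exit_cycle"])
        w.writerows(microsim_result.event_log())


def write_psa_csv(psa_result, path: str) -> None:
    psa_result.to_frame().to_csv(path, index=False)


def write_ceac_csv(curve, path: str) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_threshold_csv(grid, path: str) -> None:
    import pandas as pd

    recs = []
    for i, hr in enumerate(grid.hr_values):
        for j, cost in enumerate(grid.cost_values):
            recs.append(
                dict(hr=float(hr), cost=float(cost), winner=grid.winner[i, j],
                     inmb=grid.inmb[i, j])
            )
    pd.DataFrame.from_records(recs).to_csv(path, index=False)


def write_boundary_csv(boundary, path: str) -> None:
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["hr", "indifference_cost"])
        w.writerows(boundary)


class RunLog:
    """Append-only JSON-lines run log: one record per analysis stage with
    timestamp, seed, configuration hash and package version."""

    def __init__(self, path: str):
        self.path = path

    def record(self, stage: str, **fields) -> None:
        from . import __version__

        rec = {
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "stage": stage,
            "version": __version__,
        }
        rec.update(fields)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
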