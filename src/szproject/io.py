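"""Plain-text artifact formats.

Every stage reads and writes small CSV/JSON/YAML files so any stage can
be run, inspected or replaced independently: events as
``timestamp,probability,reported``; rate series as
``timestamp,rate,missing``; cycle regressors as
``date,period_days,sin_phase,cos_phase``; projections as
``origin_date,target_date,point,ci_low,ci_high,observed,residual``.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cycles import CycleSet
from .synthetic import CycleSpec, SimulationConfig
from .types import EventSeries, RateSeries

__all__ = [
    "read_events",
    "write_events",
    "read_rates",
    "write_rates",
    "read_sim_config",
    "write_sim_config",
    "write_cycles",
    "read_cycles_regressors",
    "write_projections",
    "read_projections",
    "write_report",
]


def read_events(path) -> EventSeries:
    return EventSeries.from_frame(pd.read_csv(path))


def write_events(events: EventSeries, path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_rates(path) -> RateSeries:
    return RateSeries.from_frame(pd.read_csv(path))


def write_rates(series: RateSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_sim_config(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["start"] = str(config.start.date())
    d["cycles"] = [[c["period_days"], c["depth"], c["phase_rad"]] for c in d["cycles"]]
    d["gap_spec"] = [list(g) for g in d["gap_spec"]]
    d["ied_cycle_gain"] = list(d["ied_cycle_gain"])
    if d["drug_transient"] is not None:
        d["drug_transient"] = list(d["drug_transient"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_sim_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "cycles" in d:
        d["cycles"] = tuple(CycleSpec(*c) for c in d["cycles"])
    if "gap_spec" in d:
        d["gap_spec"] = tuple(tuple(int(v) for v in g) for g in d["gap_spec"])
    if "ied_cycle_gain" in d:
        d["ied_cycle_gain"] = tuple(d["ied_cycle_gain"])
    if d.get("drug_transient") is not None:
        d["drug_transient"] = (int(d["drug_transient"][0]), float(d["drug_transient"][1]))
    if "start" in d:
        d["start"] = pd.Timestamp(d["start"])
    return SimulationConfig(**d)


def write_cycles(cycles: CycleSet, path) -> None:
    """Long-format cycle phases: one row per (date, period)."""
    if cycles.regressors is None:
        pd.DataFrame(columns=["date", "period_days", "sin_phase", "cos_phase"]).to_csv(
            path, index=False
        )
        return
    rows = []
    for k, T in enumerate(cycles.significant_periods):
        label = f"{float(T):g}d"
        rows.append(
            pd.DataFrame(
                {
                    "date": cycles.regressors.index,
                    "period_days": T,
                    "sin_phase": cycles.regressors[f"sin_{label}"].to_numpy(),
                    "cos_phase": cycles.regressors[f"cos_{label}"].to_numpy(),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False)


def read_cycles_regressors(path) -> pd.DataFrame:
    """Rebuild the wide (day x 2*n_periods) regressor matrix."""
    df = pd.read_csv(path, parse_dates=["date"])
    if df.empty:
        return pd.DataFrame()
    wide = {}
    for T, sub in df.groupby("period_days"):
        label = f"{float(T):g}d"
        sub = sub.set_index("date")
        wide[f"sin_{label}"] = sub["sin_phase"]
        wide[f"cos_{label}"] = sub["cos_phase"]
    return pd.DataFrame(wide)


def write_projections(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_projections(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["origin_date", "target_date"])


def write_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.Timestamp):
            return o.isoformat()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default, sort_keys=True))
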