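"""End-to-end workflow: simulate (or load) -> preprocess -> cycles ->
rolling projection -> evaluation and monitoring.

``run_pipeline`` wires the stages together under one
:class:`PipelineConfig`, writes every intermediate artifact as plain
CSV/JSON, and is deterministic under the configured seeds. The default
configuration replicates the study design on a virtual participant: a
~3-year record, a mid-recording drug change, a 369-day post-drug
training/validation span, and four 3-month test segments (two per
regimen).
"""
from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .cycles import detect_cycles
from .evaluate import (
    evaluate_segments,
    monitor_residuals,
    reporting_concordance,
    surrogate_control,
)
from .forecast import DatasetSplit, ModelOrder, fit_model, mse, rolling_projection
from .preprocess import (
    causal_moving_average,
    events_to_daily_counts,
    fill_gaps,
    filter_detections,
)
from .synthetic import SimulationConfig, VirtualParticipant, simulate_participant

__all__ = ["PipelineConfig", "PipelineResult", "default_split", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters and seeds for one pipeline run."""

    # input: either a simulation config or paths to event/IED CSVs
    simulation: Optional[SimulationConfig] = None
    events_csv: Optional[str] = None
    ied_csv: Optional[str] = None
    # preprocess
    probability_threshold: float = 0.99
    window_days: int = 90
    # cycles
    min_period: float = 1.0
    max_period: float = 45.0
    n_perm: int = 200
    fdr_level: float = 0.95
    cycles_seed: int = 1
    # forecast
    order: ModelOrder = field(default_factory=lambda: ModelOrder(5, 1, 1, use_exog=True))
    horizon: int = 14
    train_days: int = 369
    train_start_day: Optional[int] = None  # offset from series start; default: after drug change
    refit_policy: str = "fixed"
    # evaluation / monitoring
    split: Optional[DatasetSplit] = None
    n_surrogates: int = 1
    surrogate_seed: int = 2
    gapfill_seed: int = 3
    k_sd: float = 3.0
    persistence_days: int = 14
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.simulation is None and (self.events_csv is None or self.ied_csv is None):
            self.simulation = SimulationConfig()


@dataclass
class PipelineResult:
    participant: Optional[VirtualParticipant]
    smoothed: pd.Series
    cycles: object
    records: pd.DataFrame
    split: DatasetSplit
    report: object
    monitor: object
    concordance: Optional[float]


def default_split(start: pd.Timestamp, n_days: int, drug_change_day: int,
                  window_days: int = 90, train_days: int = 369) -> DatasetSplit:
    """Study-design split for a simulated record with one drug change.

    Training/validation is a ``train_days`` span beginning ~80 days after
    the drug change (clear of the titration transient); two ~3-month test
    segments sit before the change (after the smoothing warm-up) and two
    after the training span.
    """
    day = lambda k: start + pd.Timedelta(days=int(k))
    t0 = drug_change_day + 80 if (drug_change_day + 80 + train_days) < n_days - 200 else drug_change_day + 30
    pre_hi = drug_change_day
    pre_lo = max(window_days + 20, pre_hi - 200)
    mid = (pre_lo + pre_hi) // 2
    post0 = t0 + train_days
    post_mid = post0 + (n_days - post0) // 2
    return DatasetSplit(
        train_validation=(day(t0), day(t0 + train_days)),
        test_segments={
            "pre_drug_1": (day(pre_lo), day(mid)),
            "pre_drug_2": (day(mid), day(pre_hi)),
            "post_drug_1": (day(post0), day(post_mid)),
            "post_drug_2": (day(post_mid), day(n_days)),
        },
    )


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> PipelineResult:
    """Run every stage and (optionally) write the artifact directory."""
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: obtain data -------------------------------------------
    participant = None
    concordance = None
    if config.simulation is not None:
        participant = simulate_participant(config.simulation)
        events, ied = participant.seizure_events, participant.ied_rates
        concordance = (
            reporting_concordance(events, participant.diary_events) if len(events) else None
        )
        span_start = config.simulation.start
        n_days = config.simulation.n_days
        drug_day = config.simulation.drug_change_day
    else:
        events = io.read_events(config.events_csv)
        ied = io.read_rates(config.ied_csv)
        span_start = min(events.timestamps[0], ied.start).normalize()
        end = max(events.timestamps[-1], ied.index[-1])
        n_days = int(np.ceil((end - span_start) / pd.Timedelta(days=1)))
        drug_day = None
    if out and participant is not None:
        io.write_events(events, out / "events.csv")
        io.write_events(participant.diary_events, out / "diary.csv")
        io.write_rates(ied, out / "ied.csv")
        io.write_sim_config(config.simulation, out / "sim_config.yaml")

    # ---- stage 2: preprocess --------------------------------------------
    try:
        events = filter_detections(events, config.probability_threshold)
        daily = events_to_daily_counts(
            events, start_date=span_start, end_date=span_start + pd.Timedelta(days=n_days)
        )
        smoothed = causal_moving_average(daily, config.window_days)
        ied_filled = fill_gaps(ied, seed=config.gapfill_seed)
    except Exception as e:
        raise RuntimeError(f"preprocess stage failed: {e}") from e
    endog = smoothed.valid()
    if out:
        io.write_rates(smoothed.rate, out / "smoothed.csv")

    # ---- stage 3: cycles -------------------------------------------------
    try:
        from .cycles import default_period_grid

        periods = default_period_grid(config.min_period, config.max_period)
        cycles = detect_cycles(
            ied_filled,
            periods=periods,
            n_perm=config.n_perm,
            fdr_level=config.fdr_level,
            seed=config.cycles_seed,
        )
    except Exception as e:
        raise RuntimeError(f"cycles stage failed: {e}") from e
    exog = cycles.regressors
    order = config.order
    if order.use_exog and (exog is None or exog.empty):
        order = dataclasses.replace(order, use_exog=False)
    if out:
        io.write_cycles(cycles, out / "cycles.csv")

    # ---- stage 4: rolling projection ------------------------------------
    try:
        split = config.split
        if split is None:
            if drug_day is None:
                raise ValueError("no split given and none derivable without a drug-change day")
            split = default_split(span_start, n_days, drug_day, config.window_days, config.train_days)
        tr_start, tr_end = split.train_validation
        train = endog.loc[tr_start : tr_end - pd.Timedelta(days=1)]
        fit = fit_model(train, exog, order)
        first_origin = endog.index[max(order.min_window, 0)]
        roll = dict(
            refit_policy=config.refit_policy,
            params=fit.params,
            train_len=order.min_window + 1,
            first_origin=first_origin,
        )
        # h-step projections feed the MSE map and the residual monitor;
        # one-step innovations feed the rank tests (exchangeable samples)
        records = rolling_projection(endog, exog, order, horizon=config.horizon, **roll)
        records_h1 = rolling_projection(endog, exog, order, horizon=1, **roll)
    except Exception as e:
        raise RuntimeError(f"forecast stage failed: {e}") from e
    if out:
        io.write_projections(records, out / "projections.csv")
        io.write_projections(records_h1, out / "innovations.csv")

    # ---- stage 5: evaluation, surrogate, monitoring ----------------------
    try:
        report = evaluate_segments(records_h1, split, alpha=config.alpha)
        # headline per-segment MSE is that of the h-day-ahead projections
        from .evaluate import segment_residuals

        report.segment_mse = {
            k: float(np.mean(v.to_numpy() ** 2))
            for k, v in segment_residuals(records, split).items()
        }
        if config.n_surrogates > 0:
            report.surrogate = surrogate_control(
                endog,
                exog,
                order,
                split,
                seed=config.surrogate_seed,
                horizon=1,
                train_len=len(train),
            )
        targets = pd.DatetimeIndex(records["target_date"])
        in_train = (targets >= tr_start) & (targets < tr_end)
        reference = records["residual"].to_numpy()[in_train & records["residual"].notna().to_numpy()]
        monitor = monitor_residuals(
            records, reference, k_sd=config.k_sd, persistence_days=config.persistence_days
        )
    except Exception as e:
        raise RuntimeError(f"evaluate stage failed: {e}") from e

    result = PipelineResult(
        participant=participant,
        smoothed=endog,
        cycles=cycles,
        records=records,
        split=split,
        report=report,
        monitor=monitor,
        concordance=concordance,
    )
    if out:
        payload = report.to_dict()
        payload["detected_cycle_periods_days"] = cycles.significant_periods
        payload["diary_concordance_percent"] = concordance
        payload["monitor"] = {
            "ref_mean": monitor.ref_mean,
            "ref_sd": monitor.ref_sd,
            "band": list(monitor.band),
            "n_flagged_days": int(monitor.flags.sum()),
            "changepoints": [str(t.date()) for t in monitor.changepoints],
        }
        io.write_report(payload, out / "report.json")
        log = {
            "python": platform.python_version(),
            "config": _config_summary(config),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return result


def _config_summary(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"]["start"] = str(config.simulation.start)
    return d
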