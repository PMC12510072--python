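"""Virtual-participant generator.

The clinical recording the pipeline was designed for — a multi-year
sub-scalp EEG record with detected seizures and hourly interictal
epileptiform discharge (IED) rates — is not publicly available, so this
module generates virtual participants carrying the statistical structure
the analysis assumes:

* daily seizure counts from an inhomogeneous Poisson process whose
  intensity is modulated by multidien (1-45 day) cycles,
* an hourly IED rate phase-locked to the same cycles,
* an optional step change in seizure intensity when the drug regimen
  changes, with an optional short-lived titration transient,
* extended recording gaps, and
* a diary that reports only a fraction of detected events.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import EventSeries, RateSeries

__all__ = [
    "CycleSpec",
    "SimulationConfig",
    "VirtualParticipant",
    "simulate_intensity",
    "simulate_events",
    "simulate_ied_rates",
    "simulate_diary",
    "simulate_participant",
]

#: default recording start; any fixed date works, kept here so CSV round
#: trips are stable.
DEFAULT_START = pd.Timestamp("2019-11-01")


@dataclass(frozen=True)
class CycleSpec:
    """One multidien cycle: period in days, relative modulation depth and
    phase offset in radians at t=0."""

    period_days: float
    depth: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.period_days <= 45.0):
            raise ValueError("cycle period must be in [1, 45] days")
        if not (0.0 <= self.depth < 1.0):
            raise ValueError("modulation depth must be in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one virtual participant.

    The defaults emulate the study conditions the pipeline targets: a
    ~3-year recording, a few seizures per day, two dominant multidien
    cycles shared by seizures and IEDs, a mid-recording change of
    anti-seizure medication, two extended data gaps, and a diary
    reporting ~37% of detected seizures.
    """

    n_days: int = 1095
    baseline_rate: float = 3.0
    cycles: Sequence[CycleSpec] = (
        CycleSpec(20.0, 0.4, 0.0),
        CycleSpec(5.0, 0.2, 1.0),
    )
    ied_baseline: float = 60.0
    ied_cycle_gain: Sequence[float] = (0.4, 0.2)
    ied_noise_sd: float = 6.0
    drug_change_day: Optional[int] = 300
    drug_effect: float = 1.0
    drug_transient: Optional[tuple[int, float]] = None
    gap_spec: Sequence[tuple[int, int]] = ((150, 14), (250, 10))
    diary_report_prob: float = 0.3744
    start: pd.Timestamp = DEFAULT_START
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 0:
            raise ValueError("n_days must be >= 0")
        if self.baseline_rate <= 0 or self.ied_baseline <= 0:
            raise ValueError("baseline rates must be strictly positive")
        if sum(c.depth for c in self.cycles) >= 1.0:
            raise ValueError("sum of modulation depths must be < 1 to keep the intensity positive")
        if len(self.ied_cycle_gain) != len(self.cycles):
            raise ValueError("need one IED gain per cycle")
        if self.drug_effect <= 0:
            raise ValueError("drug_effect must be a positive multiplicative factor")
        if self.drug_transient is not None:
            dur, factor = self.drug_transient
            if dur < 0 or factor <= 0:
                raise ValueError("drug_transient must be (duration_days >= 0, factor > 0)")
        if not (0.0 <= self.diary_report_prob <= 1.0):
            raise ValueError("diary_report_prob must be in [0, 1]")
        spans = sorted((int(s), int(s) + int(l)) for s, l in self.gap_spec)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("gaps must be non-overlapping")
        for s, e in spans:
            if s < 0 or e > self.n_days:
                raise ValueError("gaps must lie within [0, n_days)")


@dataclass
class VirtualParticipant:
    """A generated dataset plus the configuration that produced it."""

    seizure_events: EventSeries
    ied_rates: RateSeries
    diary_events: EventSeries
    regimen_intervals: list[tuple[pd.Timestamp, pd.Timestamp, str]]
    truth: SimulationConfig


def _drug_factor(config: SimulationConfig, t_days: np.ndarray) -> np.ndarray:
    """Multiplicative regimen factor at (fractional) day t."""
    factor = np.ones_like(t_days, dtype=float)
    if config.drug_change_day is not None:
        post = t_days >= config.drug_change_day
        factor[post] = config.drug_effect
        if config.drug_transient is not None:
            dur, f = config.drug_transient
            transient = post & (t_days < config.drug_change_day + dur)
            factor[transient] = f
    return factor


def _cycle_modulation(
    cycles: Sequence[CycleSpec], gains: Sequence[float], t_days: np.ndarray
) -> np.ndarray:
    mod = np.ones_like(t_days, dtype=float)
    for cyc, g in zip(cycles, gains):
        mod += g * np.cos(2 * np.pi * t_days / cyc.period_days + cyc.phase_rad)
    return mod


def simulate_intensity(config: SimulationConfig) -> RateSeries:
    """Daily seizure intensity lambda(t), in expected seizures/day.

    lambda(t) = baseline * (1 + sum_k depth_k cos(2 pi t / T_k + phi_k))
    * drug_factor(t), evaluated at integer days t = 0..n_days-1.
    """
    t = np.arange(config.n_days, dtype=float)
    lam = config.baseline_rate * _cycle_modulation(
        config.cycles, [c.depth for c in config.cycles], t
    )
    lam *= _drug_factor(config, t)
    if config.n_days and lam.min() <= 0:
        raise ValueError("configuration yields non-positive intensity")
    return RateSeries(start=config.start, step=pd.Timedelta(days=1), values=lam)


def simulate_events(intensity: RateSeries, seed: int) -> EventSeries:
    """Draw seizure events from an inhomogeneous Poisson process.

    The daily count is Poisson(lambda(t)); event times are uniform within
    the day (no circadian structure is modelled).
    """
    rng = np.random.default_rng(seed)
    lam = intensity.values
    counts = rng.poisson(lam)
    day_idx = np.repeat(np.arange(len(lam)), counts)
    frac = rng.uniform(size=counts.sum())
    offsets = (day_idx + frac) * intensity.step
    ts = pd.DatetimeIndex(intensity.start + offsets).sort_values()
    return EventSeries(timestamps=ts)


def simulate_ied_rates(config: SimulationConfig, seed: int) -> RateSeries:
    """Hourly IED rate phase-locked to the seizure cycles.

    rate(t) = ied_baseline * (1 + sum_k gain_k cos(2 pi t / T_k + phi_k))
    plus zero-mean Gaussian noise, truncated at 0. Samples inside
    ``gap_spec`` intervals are flagged missing.
    """
    rng = np.random.default_rng(seed)
    n_hours = config.n_days * 24
    t_days = np.arange(n_hours, dtype=float) / 24.0
    rate = config.ied_baseline * _cycle_modulation(config.cycles, config.ied_cycle_gain, t_days)
    if config.ied_noise_sd > 0:
        rate = rate + rng.normal(0.0, config.ied_noise_sd, size=n_hours)
    rate = np.clip(rate, 0.0, None)
    missing = np.zeros(n_hours, dtype=bool)
    for start_day, length_days in config.gap_spec:
        missing[start_day * 24 : (start_day + length_days) * 24] = True
    return RateSeries(start=config.start, step=pd.Timedelta(hours=1), values=rate, missing=missing)


def simulate_diary(events: EventSeries, p: float, seed: int) -> EventSeries:
    """Thin detected events into a diary: each kept independently with
    probability ``p``. The result is always a subset of ``events``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("reporting probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=len(events)) < p
    return EventSeries(
        timestamps=events.timestamps[keep],
        probability=events.probability[keep],
        reported=np.ones(int(keep.sum()), dtype=bool),
    )


def simulate_participant(config: SimulationConfig) -> VirtualParticipant:
    """Generate the full virtual participant: seizures, IED rates, diary
    and regimen annotation, all driven by sub-seeds derived from
    ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    seed_events, seed_ied, seed_diary = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    intensity = simulate_intensity(config)
    events = simulate_events(intensity, seed_events)
    # mark diary membership on the master series as well
    diary = simulate_diary(events, config.diary_report_prob, seed_diary)
    reported = np.isin(events.timestamps.view("int64"), diary.timestamps.view("int64"))
    events = EventSeries(events.timestamps, events.probability, reported)
    ied = simulate_ied_rates(config, seed_ied)
    end = config.start + pd.Timedelta(days=config.n_days)
    if config.drug_change_day is None:
        regimens = [(config.start, end, "regimen-A")]
    else:
        change = config.start + pd.Timedelta(days=config.drug_change_day)
        regimens = [(config.start, change, "regimen-A"), (change, end, "regimen-B")]
    return VirtualParticipant(
        seizure_events=events,
        ied_rates=ied,
        diary_events=diary,
        regimen_intervals=regimens,
        truth=config,
    )
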