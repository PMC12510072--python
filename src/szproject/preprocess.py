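"""From raw detections to the modelling series.

The forecasting stage models a smooth long-term seizure rate; this module
produces it from the event stream in three steps: keep only high-confidence
detections, bin them into daily counts, and apply a causal 90-day moving
average. The hourly IED-rate series, which arrives with recording gaps, is
gap-filled by linear interpolation plus Gaussian white noise so that the
wavelet stage sees a complete regular grid.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import EventSeries, RateSeries, SmoothedRate

__all__ = [
    "filter_detections",
    "events_to_daily_counts",
    "fill_gaps",
    "causal_moving_average",
]

#: detector-confidence cut used in the study design: only detections with
#: >= 99% estimated probability of accuracy enter the analysis.
DEFAULT_PROBABILITY_THRESHOLD = 0.99


def filter_detections(
    events: EventSeries, threshold: float = DEFAULT_PROBABILITY_THRESHOLD
) -> EventSeries:
    """Keep events whose detector probability is >= ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    keep = events.probability >= threshold
    return EventSeries(
        timestamps=events.timestamps[keep],
        probability=events.probability[keep],
        reported=events.reported[keep],
    )


def events_to_daily_counts(
    events: EventSeries,
    start_date=None,
    end_date=None,
) -> RateSeries:
    """Bin event timestamps into calendar-day counts.

    Days are half-open ``[00:00, 24:00)`` bins anchored at midnight of
    ``start_date`` (default: the first event's day). ``end_date`` is the
    first day *not* included; default is the day after the last event.
    Events outside the range are dropped; within range the counts sum to
    the number of events.
    """
    if len(events) == 0 and (start_date is None or end_date is None):
        raise ValueError("empty event series requires explicit start and end dates")
    start = (
        pd.Timestamp(start_date).normalize()
        if start_date is not None
        else events.timestamps[0].normalize()
    )
    end = (
        pd.Timestamp(end_date).normalize()
        if end_date is not None
        else events.timestamps[-1].normalize() + pd.Timedelta(days=1)
    )
    if end < start:
        raise ValueError("end_date must be >= start_date")
    n_days = int((end - start) / pd.Timedelta(days=1))
    counts = np.zeros(n_days, dtype=float)
    if len(events):
        offsets = ((events.timestamps - start) / pd.Timedelta(days=1)).to_numpy()
        day_idx = np.floor(offsets).astype(int)
        in_range = (day_idx >= 0) & (day_idx < n_days)
        np.add.at(counts, day_idx[in_range], 1.0)
    return RateSeries(start=start, step=pd.Timedelta(days=1), values=counts)


def _noise_sd_from_first_differences(observed: np.ndarray) -> float:
    """Noise scale for gap filling: SD of first differences of the observed
    samples divided by sqrt(2), i.e. the innovation SD if the series were a
    noisy local trend."""
    if observed.size < 3:
        return 0.0
    return float(np.std(np.diff(observed), ddof=1) / np.sqrt(2.0))


def fill_gaps(series: RateSeries, seed: int = 0, noise_sd: float | None = None) -> RateSeries:
    """Fill missing runs by linear interpolation plus Gaussian white noise.

    Each missing run is replaced by the straight line between the flanking
    observed samples, plus zero-mean Gaussian noise whose SD is estimated
    from the first differences of the observed data (override with
    ``noise_sd``). Filled values are clipped at 0. Leading/trailing missing
    samples have no flanking anchors and are trimmed off. Deterministic
    under a fixed seed; a gap-free series is returned unchanged.
    """
    obs_mask = ~series.missing
    if obs_mask.sum() < 2:
        raise ValueError("need at least 2 observed samples to interpolate")
    if not series.missing.any():
        return series.copy()
    first, last = np.flatnonzero(obs_mask)[[0, -1]]
    values = series.values[first : last + 1].copy()
    missing = series.missing[first : last + 1].copy()
    start = series.start + first * series.step

    if noise_sd is None:
        noise_sd = _noise_sd_from_first_differences(values[~missing])
    rng = np.random.default_rng(seed)
    idx = np.arange(len(values), dtype=float)
    filled = np.interp(idx, idx[~missing], values[~missing])
    n_missing = int(missing.sum())
    if noise_sd > 0 and n_missing:
        filled[missing] += rng.normal(0.0, noise_sd, size=n_missing)
    filled[~missing] = values[~missing]
    filled = np.clip(filled, 0.0, None)
    return RateSeries(start=start, step=series.step, values=filled)


def causal_moving_average(daily: RateSeries, window_days: int = 90) -> SmoothedRate:
    """Causal (trailing) moving average of a daily series.

    The value at day ``t`` is the mean over days ``t-window+1 .. t``; the
    first ``window-1`` days are flagged as warm-up and excluded from
    modelling. Input must be gap-free (run :func:`fill_gaps` first).
    """
    if daily.step != pd.Timedelta(days=1):
        raise ValueError("causal_moving_average expects a daily-step series")
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if daily.missing.any():
        raise ValueError("series has missing values; fill gaps first")
    if len(daily) < window_days:
        raise ValueError("series shorter than the smoothing window")
    sm = (
        pd.Series(daily.values)
        .rolling(window=window_days, min_periods=window_days)
        .mean()
        .to_numpy()
    )
    warmup = np.zeros(len(sm), dtype=bool)
    warmup[: window_days - 1] = True
    sm[warmup] = np.nan
    out = RateSeries(start=daily.start, step=daily.step, values=sm, missing=warmup)
    return SmoothedRate(rate=out, window_days=window_days)
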