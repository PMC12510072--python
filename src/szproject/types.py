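"""Core in-memory containers shared across the pipeline.

Three containers carry data between stages: :class:`EventSeries` for
timestamped seizure detections, :class:`RateSeries` for regular-grid
numeric series (hourly IED rates, daily counts) with an explicit missing
mask, and :class:`SmoothedRate` for the causal moving-average seizure
rate that the forecasting stage models.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventSeries", "RateSeries", "SmoothedRate"]


@dataclass
class EventSeries:
    """Ordered seizure (or IED-burst) detections.

    Parameters
    ----------
    timestamps
        Non-decreasing event times.
    probability
        Detector confidence per event, in [0, 1]. Defaults to 1.0.
    reported
        Whether the event also appears in the patient diary.
    """

    timestamps: pd.DatetimeIndex
    probability: np.ndarray = None
    reported: np.ndarray = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        n = len(self.timestamps)
        if self.probability is None:
            self.probability = np.ones(n)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.reported is None:
            self.reported = np.zeros(n, dtype=bool)
        self.reported = np.asarray(self.reported, dtype=bool)
        if len(self.probability) != n or len(self.reported) != n:
            raise ValueError("probability/reported must match timestamps length")
        if n > 1 and (self.timestamps[1:] < self.timestamps[:-1]).any():
            raise ValueError("timestamps must be non-decreasing")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "probability": self.probability,
                "reported": self.reported.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSeries":
        return cls(
            timestamps=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
            probability=df.get("probability", pd.Series(np.ones(len(df)))).to_numpy(dtype=float),
            reported=df.get("reported", pd.Series(np.zeros(len(df)))).to_numpy().astype(bool),
        )


@dataclass
class RateSeries:
    """Regular-grid numeric series with an explicit gap mask.

    ``values[i]`` is the rate over ``[start + i*step, start + (i+1)*step)``.
    Missing samples are flagged in ``missing`` and their values are ignored.
    """

    start: pd.Timestamp
    step: pd.Timedelta
    values: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.step = pd.Timedelta(self.step)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.values), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.missing) != len(self.values):
            raise ValueError("missing mask must match values length")
        observed = self.values[~self.missing]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.start + self.step * np.arange(len(self.values))

    @property
    def step_days(self) -> float:
        return self.step / pd.Timedelta(days=1)

    def copy(self) -> "RateSeries":
        return RateSeries(self.start, self.step, self.values.copy(), self.missing.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.index,
                "rate": self.values,
                "missing": self.missing.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateSeries":
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        if len(ts) < 2:
            raise ValueError("need at least 2 samples to infer the step")
        step = ts[1] - ts[0]
        return cls(
            start=ts[0],
            step=step,
            values=df["rate"].to_numpy(dtype=float),
            missing=df.get("missing", pd.Series(np.zeros(len(df)))).to_numpy().astype(bool),
        )


@dataclass
class SmoothedRate:
    """Causal moving-average seizure rate (seizures/day) at daily step.

    The first ``window_days - 1`` days are warm-up: the average there would
    span fewer than ``window_days`` days, so they are flagged missing and
    excluded from model fitting.
    """

    rate: RateSeries
    window_days: int

    def __post_init__(self) -> None:
        if self.rate.step != pd.Timedelta(days=1):
            raise ValueError("SmoothedRate requires a daily-step RateSeries")
        observed = self.rate.values[~self.rate.missing]
        if observed.size and (observed < 0).any():
            raise ValueError("smoothed rates must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.rate.values

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.rate.index

    @property
    def warmup_mask(self) -> np.ndarray:
        return self.rate.missing

    def valid(self) -> pd.Series:
        """Return the post-warm-up portion as a pandas Series."""
        keep = ~self.rate.missing
        return pd.Series(self.rate.values[keep], index=self.index[keep])
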