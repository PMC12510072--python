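import warnings

import numpy as np
import pandas as pd
import pytest

from szproject.synthetic import CycleSpec, SimulationConfig, simulate_participant
from szproject.types import RateSeries

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
warnings.filterwarnings("ignore", category=FutureWarning, module="statsmodels")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact virtual participant: one year, one 20-day cycle, no drug
    change — enough structure for most unit tests at low cost."""
    return SimulationConfig(
        n_days=365,
        baseline_rate=2.0,
        cycles=(CycleSpec(20.0, 0.4, 0.0),),
        ied_cycle_gain=(0.4,),
        ied_noise_sd=3.0,
        drug_change_day=None,
        gap_spec=((100, 5),),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_participant(small_config):
    return simulate_participant(small_config)


@pytest.fixture()
def hourly_cosine():
    """Noise-free hourly series carrying a pure 20-day cosine."""

    def make(period_days=20.0, n_days=365, amplitude=1.0, mean=0.0):
        t = np.arange(n_days * 24) / 24.0
        x = mean + amplitude * np.cos(2 * np.pi * t / period_days)
        return RateSeries(pd.Timestamp("2020-01-01"), pd.Timedelta(hours=1), x)

    return make


@pytest.fixture()
def daily_series():
    def make(values, start="2020-01-01"):
        values = np.asarray(values, dtype=float)
        return RateSeries(pd.Timestamp(start), pd.Timedelta(days=1), values)

    return make
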