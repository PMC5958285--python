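import datetime

import numpy as np
import pandas as pd
import pytest

from glucoupler.cgm_ingest import DayGrid
from glucoupler.synthetic_data import SimulationConfig, generate_cohort, generate_study_cohort


def make_grid(
    values,
    date: datetime.date = datetime.date(2016, 6, 7),
    start_minute: int = 0,
    step: int = 15,
    pid: str = "P001",
) -> DayGrid:
    """Build a DayGrid from a value list (None/NaN = missing slot)."""
    vals = np.array([np.nan if v is None else float(v) for v in values])
    t0 = np.datetime64(date).astype("datetime64[m]") + start_minute
    times = t0 + np.arange(len(vals)) * step
    return DayGrid(participant_id=pid, date=date, times=times, values=vals)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_participants=4, n_days=5, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def study_cohort():
    """A small study-like cohort with missingness and nonwear applied."""
    cfg = SimulationConfig(n_participants=10, n_days=13, seed=7)
    cohort, book = generate_study_cohort(cfg)
    return cfg, cohort, book
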