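import datetime as dt

import numpy as np
import pandas as pd
import pytest

from deweather.synthetic import SyntheticWorldConfig, generate_world
from deweather.types import ScenarioPeriod


@pytest.fixture(scope="session")
def tiny_world_config() -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        seed=7, n_lat=8, n_lon=8, n_stations=60, n_high_missing=5
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_world_config):
    return generate_world(tiny_world_config)


@pytest.fixture()
def two_periods() -> list[ScenarioPeriod]:
    return [
        ScenarioPeriod("A", dt.date(2020, 1, 1), dt.date(2020, 1, 5)),
        ScenarioPeriod("B", dt.date(2020, 2, 1), dt.date(2020, 2, 5)),
    ]


def make_obs(records) -> pd.DataFrame:
    """Build a long observation frame from (station, lat, lon, ts, pm) tuples."""
    df = pd.DataFrame(records, columns=["station_id", "lat", "lon", "timestamp", "pm25"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
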