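import numpy as np
import pandas as pd
import pytest

from vegwater import ColumnParams, ColumnState, ForcingDay, SyntheticConfig


@pytest.fixture
def params():
    return ColumnParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dry_forcing():
    return ForcingDay(precipitation=0.0, air_temperature=20.0,
                      net_radiation=15.0, wind_speed=2.0,
                      surface_pressure=101.3)


@pytest.fixture
def small_config():
    """3 pixels, 3 years: the smallest valid synthetic experiment."""
    return SyntheticConfig(n_pixels=3, n_years=3, seed=7)


@pytest.fixture
def wet_state():
    return ColumnState(surface_water=2.0, s_top=10.0, s_shallow=100.0,
                       s_deep=400.0, groundwater=150.0)


def make_forcing_frame(n_days, precip=None, start="2012-01-01", tair=22.0,
                       rad=15.0, wind=2.0, pressure=95.0):
    idx = pd.date_range(start, periods=n_days, freq="D")
    if precip is None:
        precip = np.zeros(n_days)
    return pd.DataFrame({
        "precip": np.broadcast_to(np.asarray(precip, dtype=float), (n_days,)),
        "tair": np.full(n_days, tair), "rad": np.full(n_days, rad),
        "wind": np.full(n_days, wind), "pressure": np.full(n_days, pressure),
        "snow": np.zeros(n_days)}, index=idx)
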