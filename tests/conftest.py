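import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from paddyclim import synthetic
from paddyclim.config import Region, SimConfig
from paddyclim.fields import BoundingBox, GridSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def tiny_config(**overrides) -> SimConfig:
    """Small-grid study configuration for fast Monte-Carlo tests."""
    defaults = dict(
        n_years=30,
        grid=GridSpec(4.0, 22.0, 117.0, 129.0, 3.0),
        regions=(
            Region("North", BoundingBox(117, 128, 13, 22), weight=0.5),
            Region("South", BoundingBox(117, 128, 4, 13), weight=0.5),
        ),
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def enso(sim_config):
    return synthetic.gen_enso_index(sim_config)


@pytest.fixture(scope="session")
def climate_fields(sim_config, enso):
    return synthetic.gen_climate_fields(sim_config, enso)


@pytest.fixture(scope="session")
def crop_panel(sim_config, climate_fields):
    return synthetic.gen_crop_panel(sim_config, climate_fields[0])


def quarterly_series(values, start="1987Q1") -> pd.Series:
    idx = pd.period_range(start, periods=len(values), freq="Q")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def monthly_series(values, start="1987-01") -> pd.Series:
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(np.asarray(values, dtype=float), index=idx)
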