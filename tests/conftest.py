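from datetime import datetime, timezone

import numpy as np
import pytest

from fruitfst import (
    EnergyBalanceParams,
    SegmentationParams,
    WeatherRecord,
)


@pytest.fixture
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def eb_params() -> EnergyBalanceParams:
    return EnergyBalanceParams()


def random_weather_record(rng: np.random.Generator) -> WeatherRecord:
    """A random but physically valid weather record."""
    air = rng.uniform(5.0, 35.0)
    return WeatherRecord(
        timestamp=datetime(2020, 7, 15, 12, 0, tzinfo=timezone.utc),
        air_temp_c=air,
        dew_point_c=rng.uniform(-5.0, air),
        ground_temp_c=air + rng.uniform(-5.0, 25.0),
        solar_rad_wm2=rng.uniform(0.0, 1000.0),
        wind_speed_ms=rng.uniform(0.0, 8.0),
    )


def midday_record(
    air: float = 24.0,
    dew: float = 10.0,
    ground_excess: float = 20.0,
    solar: float = 900.0,
    wind: float = 1.0,
) -> WeatherRecord:
    """A clear-sky midday record typical of a sunburn-risk day."""
    return WeatherRecord(
        timestamp=datetime(2020, 7, 15, 12, 0, tzinfo=timezone.utc),
        air_temp_c=air,
        dew_point_c=dew,
        ground_temp_c=air + ground_excess,
        solar_rad_wm2=solar,
        wind_speed_ms=wind,
    )
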