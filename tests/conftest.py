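import datetime as dt

import pytest

from eaglewinter import (
    DecayModel,
    EagleModel,
    SalmonRunConfig,
    WeatherDay,
    fit_decay_temperature_model,
    load_decay_observations,
)


@pytest.fixture(scope="session")
def fitted_decay_model() -> DecayModel:
    """OLS fit of the shipped decomposition observations."""
    return fit_decay_temperature_model(load_decay_observations())


@pytest.fixture(scope="session")
def reported_decay_model() -> DecayModel:
    """Decay model at the published 2-significant-figure coefficients."""
    return DecayModel(slope=-0.0032, intercept=-0.0072, r_squared=0.80, n_obs=9)


@pytest.fixture
def default_run() -> SalmonRunConfig:
    return SalmonRunConfig()


@pytest.fixture
def eagle() -> EagleModel:
    return EagleModel()


@pytest.fixture
def make_weather_day():
    """Factory for a valid WeatherDay with overridable fields."""

    def _make(**overrides) -> WeatherDay:
        fields = dict(
            date=dt.date(2002, 1, 15),
            t_day=5.0,
            t_night=3.0,
            wind_day=3.0,
            wind_night=2.0,
            precip=4.0,
            lw_day=280.0,
            lw_night=270.0,
            daylight=9.0,
        )
        fields.update(overrides)
        return WeatherDay(**fields)

    return _make
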