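import numpy as np
import pytest

from phenorisk import DailyTemperatureGrid, SyntheticWeatherConfig, default_params, synth_weather
from phenorisk.weather import year_dates


@pytest.fixture(scope="session")
def eab():
    """Packaged emerald ash borer defaults."""
    return default_params()


def constant_weather(temp: float, shape=(1, 1), year: int = 2021, diurnal: float = 0.0):
    """A year of spatially uniform, seasonally constant weather."""
    cfg = SyntheticWeatherConfig(
        shape=shape, base=temp, amplitude=0.0, diurnal_range=diurnal,
        gradient=0.0, noise_sd=0.0, year=year,
    )
    return synth_weather(cfg)


def seeded_weather(seed: int, shape=(20, 20), year: int = 2021, **overrides):
    """A reproducible noisy synthetic-weather draw for property suites."""
    kw = dict(
        shape=shape, base=11.0, amplitude=14.0, peak_doy=200, diurnal_range=9.0,
        gradient=0.15, noise_sd=2.0, seed=seed, year=year,
    )
    kw.update(overrides)
    return synth_weather(SyntheticWeatherConfig(**kw))


def grid_from_arrays(tmin, tmax, year=2021, **kw):
    return DailyTemperatureGrid(tmin=tmin, tmax=tmax, dates=year_dates(year), **kw)


@pytest.fixture()
def const_22_2():
    """Constant 22.2 °C (10 DD/day above the 12.2 °C threshold)."""
    return constant_weather(22.2)


def shift_weather(grid: DailyTemperatureGrid, delta: float) -> DailyTemperatureGrid:
    return DailyTemperatureGrid(
        tmin=grid.tmin + delta,
        tmax=grid.tmax + delta,
        dates=grid.dates,
        transform=grid.transform,
        crs=grid.crs,
    )


def assert_event_order(events: dict, order=None) -> None:
    """Recorded DOYs must be non-decreasing along the life-cycle order."""
    from phenorisk.phenology import EVENTS

    order = order or EVENTS
    for earlier, later in zip(order[:-1], order[1:]):
        a, b = events[earlier], events[later]
        both = ~np.isnan(a) & ~np.isnan(b)
        assert np.all(a[both] <= b[both]), f"{earlier} after {later}"
        # a later event cannot occur where the earlier one never did
        assert not np.any(np.isnan(a) & ~np.isnan(b))
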