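"""Seeded synthetic winter weather for Puget Sound river mouths.

Generates daily December–February weather series whose statistical structure
emulates downscaled regional-climate output: a site- and decade-specific mean
air temperature with warming concentrated in January–February, AR(1)
persistent daily anomalies, intermittent gamma-distributed precipitation,
Weibull winds, and a bulk downward-longwave flux driven by temperature and
cloudiness. Day/night partitioning uses astronomical photoperiod.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "STEFAN_BOLTZMANN",
    "WeatherDay",
    "ClimateScenario",
    "daylight_hours",
    "generate_winter_weather",
    "default_scenarios",
    "read_weather_csv",
    "write_weather_csv",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4

#: Columns of the weather CSV interchange format, in order.
WEATHER_CSV_COLUMNS = [
    "date",
    "t_day_C",
    "t_night_C",
    "wind_day_ms",
    "wind_night_ms",
    "precip_mm",
    "lw_day_Wm2",
    "lw_night_Wm2",
    "daylight_h",
]


@dataclass(frozen=True)
class WeatherDay:
    """One winter day's day/night-partitioned weather drivers.

    Temperatures are 2-m air temperature (°C), winds 10-m wind speed
    (m s⁻¹), ``precip`` total daily precipitation (mm), ``lw_*`` downward
    longwave flux (W m⁻²) and ``daylight`` the photoperiod in hours.
    """

    date: dt.date
    t_day: float
    t_night: float
    wind_day: float
    wind_night: float
    precip: float
    lw_day: float
    lw_night: float
    daylight: float

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError(f"precip must be >= 0, got {self.precip}")
        if not (0.0 < self.daylight < 24.0):
            raise ValueError(f"daylight must lie in (0, 24), got {self.daylight}")
        if self.lw_day <= 0 or self.lw_night <= 0:
            raise ValueError("downward longwave fluxes must be positive")

    @property
    def t_mean(self) -> float:
        """Daylight-weighted daily mean temperature (°C)."""
        f = self.daylight / 24.0
        return f * self.t_day + (1.0 - f) * self.t_night


@dataclass(frozen=True)
class ClimateScenario:
    """Parameters of one synthetic site × decade × model-analog winter climate.

    ``month_offsets`` holds the decade warming offsets (°C) applied in
    December, January and February respectively; concentrating warming in
    Jan–Feb is expressed by larger second and third entries.
    """

    site: str = "custom"
    decade: str = "custom"
    model: str = "custom"
    latitude: float = 47.5
    winter_mean_C: float = 4.0
    month_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ar1_coeff: float = 0.7
    anomaly_sd: float = 3.0
    diurnal_range: float = 2.0
    wet_day_prob: float = 0.6
    precip_shape: float = 0.8
    precip_scale_mm: float = 12.0
    weibull_shape: float = 1.8
    weibull_scale: float = 3.5
    eps_clear: float = 0.70
    eps_cloud: float = 0.20
    cloud_mean: float = 0.75
    cloud_sd: float = 0.15
    start_year: int = 2001
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ValueError(f"ar1_coeff must lie in [0, 1), got {self.ar1_coeff}")
        if self.anomaly_sd < 0:
            raise ValueError(f"anomaly_sd must be >= 0, got {self.anomaly_sd}")
        if not (0.0 <= self.wet_day_prob <= 1.0):
            raise ValueError(f"wet_day_prob must lie in [0, 1], got {self.wet_day_prob}")
        if not (0.0 < self.latitude < 66.0):
            raise ValueError(
                f"latitude must lie in (0, 66) degrees N, got {self.latitude}"
            )

    def with_seed(self, seed: int) -> "ClimateScenario":
        return replace(self, seed=seed)


def _solar_declination(date: dt.date) -> float:
    """Solar declination (radians) from the day of year (cosine approximation)."""
    doy = date.timetuple().tm_yday
    return math.radians(-23.44 * math.cos(2.0 * math.pi * (doy + 10) / 365.0))


def daylight_hours(date: dt.date, latitude: float) -> float:
    """Astronomical day length in hours.

    Uses the sunset-hour-angle formula with the conventional 90.833° solar
    zenith at sunrise/sunset (solar-disk radius plus atmospheric refraction),
    matching standard solar-geometry calculators.

    Parameters
    ----------
    date : datetime.date
    latitude : float
        Degrees north, restricted to (0, 66): poleward of ~66° the sun can
        fail to rise or set in winter and the formula has no solution.
    """
    if not (0.0 < latitude < 66.0):
        raise ValueError(
            f"latitude must lie in (0, 66) degrees N (no polar day/night), got {latitude}"
        )
    phi = math.radians(latitude)
    delta = _solar_declination(date)
    zenith = math.radians(90.833)
    cos_h0 = (math.cos(zenith) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    cos_h0 = min(1.0, max(-1.0, cos_h0))
    return 24.0 / math.pi * math.acos(cos_h0)


def winter_dates(start_year: int = 2001) -> list[dt.date]:
    """The 90 calendar days Dec 1 – Feb 28 (Feb 29 never included)."""
    start = dt.date(start_year, 12, 1)
    return [start + dt.timedelta(days=i) for i in range(90)]


def _month_offset(scenario: ClimateScenario, date: dt.date) -> float:
    return {12: scenario.month_offsets[0],
            1: scenario.month_offsets[1],
            2: scenario.month_offsets[2]}[date.month]


def _longwave(t_c: float, emissivity: float) -> float:
    t_k = t_c + 273.15
    return emissivity * STEFAN_BOLTZMANN * t_k**4


def generate_winter_weather(
    scenario: ClimateScenario, seed: int | None = None
) -> list[WeatherDay]:
    """Generate one seeded 90-day winter (Dec 1 – Feb 28) of daily weather.

    Daily mean temperature is ``winter_mean + month offset + AR(1) anomaly``;
    the anomaly process is stationary with standard deviation ``anomaly_sd``
    and lag-1 autocorrelation ``ar1_coeff``. The mean is split into day and
    night values by the diurnal range weighted so the daylight-weighted mean
    is conserved. Precipitation is Bernoulli occurrence times a gamma amount;
    winds are Weibull; downward longwave is a bulk effective-emissivity
    formula with cloud fraction boosted on wet days.

    The same seed always reproduces the identical series, and the random
    streams are consumed independently of the temperature parameters, so two
    scenarios differing only in mean/offsets share their anomalies exactly.
    """
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise ValueError("a seed is required: set scenario.seed or pass seed=")
    rng = np.random.default_rng(seed)
    dates = winter_dates(scenario.start_year)
    n = len(dates)

    rho, sd = scenario.ar1_coeff, scenario.anomaly_sd
    z = rng.standard_normal(n)
    anomalies = np.empty(n)
    anomalies[0] = sd * z[0]
    innov_sd = sd * math.sqrt(max(0.0, 1.0 - rho**2))
    for i in range(1, n):
        anomalies[i] = rho * anomalies[i - 1] + innov_sd * z[i]

    wet = rng.random(n) < scenario.wet_day_prob
    amounts = rng.gamma(scenario.precip_shape, scenario.precip_scale_mm, size=n)
    precip = np.where(wet, amounts, 0.0)
    wind_day = scenario.weibull_scale * rng.weibull(scenario.weibull_shape, size=n)
    wind_night = scenario.weibull_scale * rng.weibull(scenario.weibull_shape, size=n)
    cloud_noise = rng.normal(0.0, scenario.cloud_sd, size=n)

    days: list[WeatherDay] = []
    for i, date in enumerate(dates):
        t_mean = scenario.winter_mean_C + _month_offset(scenario, date) + anomalies[i]
        dl = daylight_hours(date, scenario.latitude)
        f = dl / 24.0
        t_day = t_mean + scenario.diurnal_range * (1.0 - f)
        t_night = t_mean - scenario.diurnal_range * f
        cloud = scenario.cloud_mean + (0.15 if wet[i] else -0.05) + cloud_noise[i]
        cloud = min(1.0, max(0.0, cloud))
        eps = scenario.eps_clear + scenario.eps_cloud * cloud
        days.append(
            WeatherDay(
                date=date,
                t_day=t_day,
                t_night=t_night,
                wind_day=float(wind_day[i]),
                wind_night=float(wind_night[i]),
                precip=float(precip[i]),
                lw_day=_longwave(t_day, eps),
                lw_night=_longwave(t_night, eps),
                daylight=dl,
            )
        )
    return days


# Site presets: approximate river-mouth latitudes; winter means ordered
# Nisqually > Skagit > Hamma Hamma; Nisqually driest.
_SITE_PARAMS = {
    "Skagit": dict(latitude=48.4, winter_mean_C=4.0, wet_day_prob=0.60,
                   precip_scale_mm=12.0),
    "HammaHamma": dict(latitude=47.55, winter_mean_C=3.0, wet_day_prob=0.65,
                       precip_scale_mm=14.0),
    "Nisqually": dict(latitude=47.1, winter_mean_C=5.0, wet_day_prob=0.50,
                      precip_scale_mm=9.0),
}

# Decade warming offsets (Dec, Jan, Feb): warming concentrated in Jan–Feb.
_DECADE_OFFSETS = {"1970s": (0.0, 0.0, 0.0), "2050s": (1.0, 2.5, 2.5)}
# 2050s winters slightly less cloudy.
_DECADE_CLOUD = {"1970s": 0.75, "2050s": 0.70}

# Model analog A runs warmer and drier than B (two downscaled GCM forcings).
_MODEL_PARAMS = {
    "A": dict(mean_shift=0.5, wet_shift=-0.05),
    "B": dict(mean_shift=0.0, wet_shift=0.0),
}

SITES = tuple(_SITE_PARAMS)
DECADES = tuple(_DECADE_OFFSETS)
MODELS = tuple(_MODEL_PARAMS)


def make_scenario(site: str, decade: str, model: str,
                  seed: int | None = None) -> ClimateScenario:
    """Build the preset scenario for one site × decade × model-analog cell."""
    try:
        sp = _SITE_PARAMS[site]
        offsets = _DECADE_OFFSETS[decade]
        mp = _MODEL_PARAMS[model]
    except KeyError as exc:
        raise ValueError(f"unknown preset label: {exc.args[0]!r}") from None
    return ClimateScenario(
        site=site,
        decade=decade,
        model=model,
        latitude=sp["latitude"],
        winter_mean_C=sp["winter_mean_C"] + mp["mean_shift"],
        month_offsets=offsets,
        wet_day_prob=sp["wet_day_prob"] + mp["wet_shift"],
        precip_scale_mm=sp["precip_scale_mm"],
        cloud_mean=_DECADE_CLOUD[decade],
        seed=seed,
    )


def default_scenarios() -> list[ClimateScenario]:
    """All 12 presets: 3 sites × 2 decades × 2 model analogs (seeds unset)."""
    return [
        make_scenario(site, decade, model)
        for model in MODELS
        for site in SITES
        for decade in DECADES
    ]


def _to_frame(days: list[WeatherDay]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in days],
            "t_day_C": [d.t_day for d in days],
            "t_night_C": [d.t_night for d in days],
            "wind_day_ms": [d.wind_day for d in days],
            "wind_night_ms": [d.wind_night for d in days],
            "precip_mm": [d.precip for d in days],
            "lw_day_Wm2": [d.lw_day for d in days],
            "lw_night_Wm2": [d.lw_night for d in days],
            "daylight_h": [d.daylight for d in days],
        }
    )


def write_weather_csv(days: list[WeatherDay], path) -> None:
    """Write a weather series in the CSV interchange schema."""
    _to_frame(days).to_csv(path, index=False)


def read_weather_csv(path) -> list[WeatherDay]:
    """Read and validate a weather series CSV.

    Raises ``ValueError`` naming the offending row (1-based data row number)
    for non-numeric cells, negative precipitation or date gaps; missing
    columns and empty files are rejected up front.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in WEATHER_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {', '.join(missing)}")
    if len(frame) == 0:
        raise ValueError("weather CSV contains no records")

    days: list[WeatherDay] = []
    prev_date: dt.date | None = None
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            date = dt.date.fromisoformat(row.date)
            values = {
                col: float(getattr(row, col)) for col in WEATHER_CSV_COLUMNS[1:]
            }
        except (TypeError, ValueError) as exc:
            raise ValueError(f"weather CSV row {idx}: unparseable value ({exc})") from None
        if values["precip_mm"] < 0:
            raise ValueError(f"weather CSV row {idx}: negative precipitation")
        if prev_date is not None and (date - prev_date).days != 1:
            raise ValueError(
                f"weather CSV row {idx}: date gap ({prev_date} -> {date})"
            )
        prev_date = date
        try:
            days.append(
                WeatherDay(
                    date=date,
                    t_day=values["t_day_C"],
                    t_night=values["t_night_C"],
                    wind_day=values["wind_day_ms"],
                    wind_night=values["wind_night_ms"],
                    precip=values["precip_mm"],
                    lw_day=values["lw_day_Wm2"],
                    lw_night=values["lw_night_Wm2"],
                    daylight=values["daylight_h"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"weather CSV row {idx}: {exc}") from None
    return days
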