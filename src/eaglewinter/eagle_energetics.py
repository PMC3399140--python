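"""Daily food-consumption bioenergetics of an overwintering bald eagle.

The model is an energy balance at constant body mass: daily energy
expenditure is the activity-budget-weighted sum of metabolic heat production
in each behavioural state (feeding/waiting on gravel bars, daytime perching,
nighttime roosting, flapping flight, gliding flight), each state costed with
that phase's (day or night) weather; required food intake is expenditure
divided by the diet's metabolizable energy density. Thermoregulatory
surcharges are linear in cold (below the lower critical temperature), wind,
precipitation, and the downward-longwave radiation deficit; flight costs are
fixed multipliers of basal metabolic rate.

All constants are configuration, not code: the defaults below are documented
choices (see docs/methods.md), tuned for plausibility rather than taken from
any single calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate_synth import STEFAN_BOLTZMANN, WeatherDay

__all__ = [
    "ActivityBudget",
    "EagleModel",
    "DailyConsumption",
    "SeasonConsumption",
    "bmr",
    "smr",
    "metabolic_heat",
    "daily_consumption",
    "season_consumption",
]

_BUDGET_TOL = 1e-9


@dataclass(frozen=True)
class ActivityBudget:
    """Fractions of the 24-h day spent in each behavioural state.

    ``f_gb`` feeding/waiting on gravel bars, ``f_p`` daytime perching,
    ``f_r`` nighttime roosting, ``f_af`` active (flapping) flight, ``f_pf``
    passive (gliding) flight. Fractions must be nonnegative and sum to 1.
    """

    f_gb: float
    f_p: float
    f_r: float
    f_af: float
    f_pf: float

    def __post_init__(self) -> None:
        fracs = (self.f_gb, self.f_p, self.f_r, self.f_af, self.f_pf)
        if any(f < 0 for f in fracs):
            raise ValueError("activity fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > _BUDGET_TOL:
            raise ValueError(f"activity fractions must sum to 1, got {sum(fracs)}")

    @classmethod
    def from_photoperiod(
        cls,
        daylight: float,
        gb_frac: float = 0.35,
        perch_frac: float = 0.55,
        active_flight_frac: float = 0.04,
        passive_flight_frac: float = 0.06,
    ) -> "ActivityBudget":
        """Daily budget with all night spent roosting and daylight divided
        among the four daytime states by the given within-daylight fractions
        (defaults sum to 1)."""
        day_frac = daylight / 24.0
        total = gb_frac + perch_frac + active_flight_frac + passive_flight_frac
        if abs(total - 1.0) > _BUDGET_TOL:
            raise ValueError("within-daylight fractions must sum to 1")
        return cls(
            f_gb=day_frac * gb_frac,
            f_p=day_frac * perch_frac,
            f_r=1.0 - day_frac,
            f_af=day_frac * active_flight_frac,
            f_pf=day_frac * passive_flight_frac,
        )


@dataclass(frozen=True)
class EagleModel:
    """Bald eagle bioenergetics parameters.

    ``wme`` is the diet metabolizable energy density in kJ per gram wet mass
    of chum salmon carcass. The basal rate follows a nonpasserine allometry,
    ``bmr_coeff · mass^bmr_exponent`` kJ·day⁻¹. Thermoregulatory surcharge
    slopes are per °C below ``t_lc``, per m·s⁻¹ wind, per mm·day⁻¹
    precipitation, and per W·m⁻² of downward-longwave deficit relative to
    blackbody flux at air temperature. Flight costs are 12.5× (flapping) and
    3.5× (gliding) BMR.
    """

    mass: float = 4.5  # kg
    wme: float = 3.764  # kJ per g wet mass
    bmr_coeff: float = 327.6  # kJ day^-1 kg^-bmr_exponent
    bmr_exponent: float = 0.723
    t_lc: float = 10.0  # °C lower critical temperature
    cold_slope: float = 4.0  # kJ kg^-1 day^-1 per °C below t_lc
    wind_coeff: float = 3.0  # kJ kg^-1 day^-1 per m s^-1
    precip_coeff: float = 0.5  # kJ kg^-1 day^-1 per mm day^-1
    lw_coeff: float = 0.1  # kJ kg^-1 day^-1 per W m^-2 deficit
    active_mult: float = 12.5  # flapping flight, × BMR
    passive_mult: float = 3.5  # gliding flight, × BMR
    activity_mult: float = 2.0  # active SMR as a multiple of resting SMR
    carcass_edible_mass_g: float = 3652.0  # g wet mass per carcass

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.wme <= 0:
            raise ValueError("wme must be > 0")
        if not (self.active_mult > self.passive_mult > 1.0):
            raise ValueError("flight multipliers must satisfy active > passive > 1")


@dataclass(frozen=True)
class DailyConsumption:
    """One day's food requirement with a per-activity energy breakdown."""

    c_grams: float  # g wet mass per bird per day
    c_energy: float  # kJ per bird per day
    wmi: float  # wet matter intake, g per kg body mass per day
    components: dict[str, float] = field(default_factory=dict)  # kJ by activity


@dataclass(frozen=True)
class SeasonConsumption:
    """Winter totals of energy and food intake for one eagle."""

    total_kj: float
    total_grams: float
    carcass_equivalents: float
    daily: tuple[DailyConsumption, ...]


def bmr(model: EagleModel) -> float:
    """Mass-specific basal metabolic rate, kJ·kg⁻¹·day⁻¹."""
    return model.bmr_coeff * model.mass**model.bmr_exponent / model.mass


def smr(model: EagleModel, temperature: float, state: str = "rest") -> float:
    """Standard metabolic rate at a given air temperature, kJ·kg⁻¹·day⁻¹.

    Resting SMR equals BMR at or above the lower critical temperature and
    rises linearly below it; the active state multiplies the resting value.
    """
    base = bmr(model) + model.cold_slope * max(0.0, model.t_lc - temperature)
    if state == "rest":
        return base
    if state == "active":
        return model.activity_mult * base
    raise ValueError(f"state must be 'active' or 'rest', got {state!r}")


def _lw_deficit(temperature: float, lw: float) -> float:
    t_k = temperature + 273.15
    return max(0.0, STEFAN_BOLTZMANN * t_k**4 - lw)


def metabolic_heat(
    model: EagleModel,
    temperature: float,
    wind: float,
    precip: float,
    lw: float,
    phase: str = "day",
    state: str | None = None,
) -> float:
    """Metabolic heat production under weather stress, kJ·kg⁻¹·day⁻¹.

    SMR (active by day, resting by night unless ``state`` overrides) plus
    nonnegative linear surcharges for wind, precipitation, and the downward
    longwave deficit relative to blackbody flux at air temperature.
    """
    if wind < 0 or precip < 0:
        raise ValueError("wind and precipitation must be >= 0")
    if lw <= 0:
        raise ValueError("downward longwave flux must be positive")
    if phase not in ("day", "night"):
        raise ValueError(f"phase must be 'day' or 'night', got {phase!r}")
    if state is None:
        state = "active" if phase == "day" else "rest"
    return (
        smr(model, temperature, state)
        + model.wind_coeff * wind
        + model.precip_coeff * precip
        + model.lw_coeff * _lw_deficit(temperature, lw)
    )


def daily_consumption(
    model: EagleModel, day: WeatherDay, budget: ActivityBudget
) -> DailyConsumption:
    """Food required to hold body mass constant through one winter day.

    Mass-specific expenditure is the activity-weighted sum: gravel-bar time
    at active metabolic heat under daytime weather, perching at resting heat
    under daytime weather, roosting at resting heat under nighttime weather,
    and the two flight states at their BMR multipliers (flight costs bypass
    the weather surcharges). Energy intake equals expenditure; grams follow
    by dividing by the diet energy density.
    """
    b = bmr(model)
    m_gb = metabolic_heat(
        model, day.t_day, day.wind_day, day.precip, day.lw_day, "day", "active"
    )
    m_perch = metabolic_heat(
        model, day.t_day, day.wind_day, day.precip, day.lw_day, "day", "rest"
    )
    m_roost = metabolic_heat(
        model, day.t_night, day.wind_night, day.precip, day.lw_night, "night", "rest"
    )
    components = {
        "gb_kJ": budget.f_gb * m_gb * model.mass,
        "perch_kJ": budget.f_p * m_perch * model.mass,
        "roost_kJ": budget.f_r * m_roost * model.mass,
        "af_kJ": budget.f_af * model.active_mult * b * model.mass,
        "pf_kJ": budget.f_pf * model.passive_mult * b * model.mass,
    }
    c_energy = sum(components.values())
    c_grams = c_energy / model.wme
    return DailyConsumption(
        c_grams=c_grams,
        c_energy=c_energy,
        wmi=c_grams / model.mass,
        components=components,
    )


def season_consumption(
    model: EagleModel,
    weather: list[WeatherDay],
    budget_policy=None,
) -> SeasonConsumption:
    """Winter-total energy and food intake over a full weather series.

    ``budget_policy`` maps a WeatherDay to an ActivityBudget; the default
    recomputes the budget each day from photoperiod (all night roosting).
    """
    if budget_policy is None:
        budget_policy = lambda d: ActivityBudget.from_photoperiod(d.daylight)
    daily = tuple(daily_consumption(model, d, budget_policy(d)) for d in weather)
    total_kj = float(sum(d.c_energy for d in daily))
    total_g = float(sum(d.c_grams for d in daily))
    return SeasonConsumption(
        total_kj=total_kj,
        total_grams=total_g,
        carcass_equivalents=total_g / model.carcass_edible_mass_g,
        daily=daily,
    )
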