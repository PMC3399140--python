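"""Eagle bioenergetics: metabolic sub-models, daily consumption, season totals."""

import dataclasses
import math

import pytest

from eaglewinter.climate_synth import (
    STEFAN_BOLTZMANN,
    ClimateScenario,
    generate_winter_weather,
)
from eaglewinter.eagle_energetics import (
    ActivityBudget,
    EagleModel,
    bmr,
    daily_consumption,
    metabolic_heat,
    season_consumption,
    smr,
)


def _blackbody(t_c: float) -> float:
    return STEFAN_BOLTZMANN * (t_c + 273.15) ** 4


def _neutral_day(make_weather_day, model: EagleModel):
    """Thermoneutral, calm, dry day with zero longwave deficit both phases."""
    return make_weather_day(
        t_day=model.t_lc,
        t_night=model.t_lc,
        wind_day=0.0,
        wind_night=0.0,
        precip=0.0,
        lw_day=_blackbody(model.t_lc),
        lw_night=_blackbody(model.t_lc),
    )


class TestBmr:
    def test_linear_in_coefficient(self, eagle):
        doubled = dataclasses.replace(eagle, bmr_coeff=2 * eagle.bmr_coeff)
        assert bmr(doubled) == pytest.approx(2 * bmr(eagle), rel=1e-12)

    def test_default_allometry_value(self, eagle):
        """327.6 · 4.5^0.723 / 4.5 kJ·kg⁻¹·day⁻¹, hand-computed."""
        assert bmr(eagle) == pytest.approx(327.6 * 4.5**0.723 / 4.5, rel=1e-12)

    def test_exponent_one_removes_mass_dependence(self, eagle):
        small = dataclasses.replace(eagle, bmr_exponent=1.0, mass=3.0)
        large = dataclasses.replace(eagle, bmr_exponent=1.0, mass=6.0)
        assert bmr(small) == pytest.approx(bmr(large), rel=1e-12)


class TestSmr:
    def test_resting_equals_bmr_at_thermoneutrality(self, eagle):
        assert smr(eagle, eagle.t_lc, "rest") == pytest.approx(bmr(eagle))
        assert smr(eagle, eagle.t_lc + 5, "rest") == pytest.approx(bmr(eagle))

    def test_cold_raises_resting_rate(self, eagle):
        assert smr(eagle, eagle.t_lc - 10, "rest") > smr(eagle, eagle.t_lc, "rest")

    def test_continuity_at_lower_critical_temperature(self, eagle):
        below = smr(eagle, eagle.t_lc - 1e-9, "rest")
        assert below == pytest.approx(smr(eagle, eagle.t_lc, "rest"), rel=1e-9)

    @pytest.mark.parametrize("temp", [-10.0, 0.0, 10.0, 20.0])
    def test_active_is_multiple_of_resting(self, eagle, temp):
        assert smr(eagle, temp, "active") == pytest.approx(
            eagle.activity_mult * smr(eagle, temp, "rest"), rel=1e-12
        )

    def test_unknown_state_rejected(self, eagle):
        with pytest.raises(ValueError, match="state"):
            smr(eagle, 5.0, "soaring")


class TestMetabolicHeat:
    def test_all_stressors_neutral_reduces_to_bmr(self, eagle):
        m = metabolic_heat(
            eagle, eagle.t_lc, 0.0, 0.0, _blackbody(eagle.t_lc), phase="night"
        )
        assert m == pytest.approx(bmr(eagle), rel=1e-12)

    def test_monotone_in_each_stressor(self, eagle):
        args = dict(temperature=2.0, wind=3.0, precip=5.0, lw=280.0, phase="night")
        base = metabolic_heat(eagle, **args)
        assert metabolic_heat(eagle, **{**args, "wind": 10.0}) > base
        assert metabolic_heat(eagle, **{**args, "precip": 15.0}) > base
        assert metabolic_heat(eagle, **{**args, "lw": 200.0}) > base
        assert metabolic_heat(eagle, **{**args, "lw": 340.0}) <= base

    def test_non_increasing_in_temperature_below_t_lc(self, eagle):
        temps = [-10.0, -5.0, 0.0, 5.0, 9.0, 10.0]
        values = [
            metabolic_heat(eagle, t, 2.0, 3.0, 250.0, phase="night") for t in temps
        ]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_day_phase_defaults_to_active_state(self, eagle):
        day = metabolic_heat(eagle, 5.0, 0.0, 0.0, _blackbody(5.0), phase="day")
        night = metabolic_heat(eagle, 5.0, 0.0, 0.0, _blackbody(5.0), phase="night")
        assert day == pytest.approx(eagle.activity_mult * night, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(wind=-1.0), dict(precip=-1.0), dict(lw=0.0)])
    def test_invalid_weather_rejected(self, eagle, kwargs):
        args = dict(temperature=5.0, wind=1.0, precip=1.0, lw=280.0, phase="day")
        with pytest.raises(ValueError):
            metabolic_heat(eagle, **{**args, **kwargs})


class TestDailyConsumption:
    def test_all_night_rest_reduces_to_bmr_balance(self, eagle, make_weather_day):
        """An eagle roosting 24 h at thermoneutral calm: C = mass·BMR/WME."""
        day = _neutral_day(make_weather_day, eagle)
        budget = ActivityBudget(f_gb=0, f_p=0, f_r=1.0, f_af=0, f_pf=0)
        result = daily_consumption(eagle, day, budget)
        assert result.c_grams == pytest.approx(
            eagle.mass * bmr(eagle) / eagle.wme, rel=1e-12
        )
        assert result.wmi == pytest.approx(result.c_grams / eagle.mass, rel=1e-12)

    def test_budget_shift_between_flight_modes_is_linear(
        self, eagle, make_weather_day
    ):
        day = make_weather_day()
        b0 = ActivityBudget(f_gb=0.1, f_p=0.2, f_r=0.6, f_af=0.02, f_pf=0.08)
        b1 = ActivityBudget(f_gb=0.1, f_p=0.2, f_r=0.6, f_af=0.03, f_pf=0.07)
        delta = (
            daily_consumption(eagle, day, b1).c_grams
            - daily_consumption(eagle, day, b0).c_grams
        )
        expected = eagle.mass * 0.01 * (12.5 - 3.5) * bmr(eagle) / eagle.wme
        assert delta == pytest.approx(expected, rel=1e-9)

    def test_components_sum_to_total(self, eagle, make_weather_day):
        day = make_weather_day()
        budget = ActivityBudget.from_photoperiod(day.daylight)
        result = daily_consumption(eagle, day, budget)
        assert sum(result.components.values()) == pytest.approx(
            result.c_energy, rel=1e-12
        )
        assert all(v >= 0 for v in result.components.values())

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ActivityBudget(f_gb=0.5, f_p=0.5, f_r=0.5, f_af=0.0, f_pf=0.0)
        with pytest.raises(ValueError, match=">= 0"):
            ActivityBudget(f_gb=-0.1, f_p=0.5, f_r=0.6, f_af=0.0, f_pf=0.0)

    @pytest.mark.parametrize(
        "t_day, t_night, wind_day, wind_night, precip, lw_day, lw_night, daylight",
        [
            (5.0, 3.0, 3.0, 2.0, 4.0, 280.0, 270.0, 9.0),
            (-2.0, -4.0, 6.0, 5.0, 0.0, 240.0, 230.0, 8.3),
            (8.0, 6.0, 1.0, 0.5, 12.0, 310.0, 300.0, 10.0),
            (12.0, 9.0, 0.0, 0.0, 0.0, 330.0, 320.0, 11.0),
            (0.0, -1.0, 4.0, 4.0, 25.0, 260.0, 255.0, 8.5),
        ],
    )
    def test_matches_independent_hand_calculation(
        self, eagle, make_weather_day,
        t_day, t_night, wind_day, wind_night, precip, lw_day, lw_night, daylight,
    ):
        """Five fixture days against a spelled-out arithmetic evaluation of the
        documented default formula (independent of the implementation)."""
        day = make_weather_day(
            t_day=t_day, t_night=t_night, wind_day=wind_day, wind_night=wind_night,
            precip=precip, lw_day=lw_day, lw_night=lw_night, daylight=daylight,
        )
        budget = ActivityBudget.from_photoperiod(daylight)
        result = daily_consumption(eagle, day, budget)

        # -- independent evaluation, default constants as literals --
        sigma = 5.670374419e-8
        b = 327.6 * 4.5**0.723 / 4.5
        rest_day = b + 4.0 * max(0.0, 10.0 - t_day)
        rest_night = b + 4.0 * max(0.0, 10.0 - t_night)
        deficit_day = max(0.0, sigma * (t_day + 273.15) ** 4 - lw_day)
        deficit_night = max(0.0, sigma * (t_night + 273.15) ** 4 - lw_night)
        stress_day = 3.0 * wind_day + 0.5 * precip + 0.1 * deficit_day
        stress_night = 3.0 * wind_night + 0.5 * precip + 0.1 * deficit_night
        m_gb = 2.0 * rest_day + stress_day
        m_perch = rest_day + stress_day
        m_roost = rest_night + stress_night
        f = daylight / 24.0
        per_kg = (
            f * 0.35 * m_gb
            + f * 0.55 * m_perch
            + (1.0 - f) * m_roost
            + f * 0.04 * 12.5 * b
            + f * 0.06 * 3.5 * b
        )
        expected_grams = 4.5 * per_kg / 3.764
        assert result.c_grams == pytest.approx(expected_grams, rel=1e-6)


class TestSeasonConsumption:
    def test_constant_weather_is_additive(self, eagle, make_weather_day):
        day = make_weather_day()
        season = season_consumption(eagle, [day] * 90)
        single = daily_consumption(
            eagle, day, ActivityBudget.from_photoperiod(day.daylight)
        )
        assert season.total_kj == pytest.approx(90 * single.c_energy, rel=1e-12)
        assert season.total_grams == pytest.approx(90 * single.c_grams, rel=1e-12)
        assert season.carcass_equivalents == pytest.approx(
            season.total_grams / eagle.carcass_edible_mass_g, rel=1e-12
        )

    def test_uniform_warming_lowers_demand(self, eagle, make_weather_day):
        day = make_weather_day(t_day=4.0, t_night=2.0)
        warm = dataclasses.replace(day, t_day=6.0, t_night=4.0)
        cold_total = season_consumption(eagle, [day] * 90).total_kj
        warm_total = season_consumption(eagle, [warm] * 90).total_kj
        assert warm_total < cold_total

    def test_paired_seed_decade_warming_gives_small_decline(self, eagle):
        """+2.5 °C with shared weather noise: demand falls, but only by a few
        percent — the food-supply side dwarfs the demand side."""
        base = ClimateScenario(winter_mean_C=5.0, seed=42)
        warm = dataclasses.replace(base, month_offsets=(2.5, 2.5, 2.5))
        past = season_consumption(eagle, generate_winter_weather(base)).total_kj
        future = season_consumption(eagle, generate_winter_weather(warm)).total_kj
        decline_pct = 100.0 * (past - future) / past
        assert 0.0 < decline_pct < 10.0

    def test_mass_scaling_with_unit_exponent(self, make_weather_day):
        """With BMR exponent 1 every term is mass-specific: C ∝ mass."""
        day = make_weather_day()
        small = EagleModel(mass=4.5, bmr_exponent=1.0)
        large = EagleModel(mass=9.0, bmr_exponent=1.0)
        c_small = season_consumption(small, [day] * 10).total_grams
        c_large = season_consumption(large, [day] * 10).total_grams
        assert c_large == pytest.approx(2 * c_small, rel=1e-12)


class TestModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mass=0.0),
            dict(wme=0.0),
            dict(active_mult=3.0, passive_mult=3.5),
            dict(passive_mult=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EagleModel(**kwargs)
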