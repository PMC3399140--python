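"""Factorial scenario experiment: models × sites × decades × years.

Runs the synthetic-weather generator, the eagle bioenergetics model, and the
carcass-pool simulation for every cell of a scenario grid (default 2 climate
model analogs × 3 rivers × 2 decades × 10 winters = 120 simulations), with
per-cell seeds derived reproducibly from a single base seed. Emits tidy
per-month tables ready for external statistics packages and decade contrasts
of consumption and carcass biomass.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climate_synth
from .climate_synth import WeatherDay, generate_winter_weather
from .decay import DecayModel, fit_decay_temperature_model, load_decay_observations
from .eagle_energetics import EagleModel, SeasonConsumption, season_consumption
from .salmon_run import (
    BiomassTrajectory,
    SalmonRunConfig,
    daily_mean_temperatures,
    seasonal_summary,
    simulate_carcass_biomass,
)

__all__ = [
    "ScenarioGrid",
    "ScenarioResult",
    "cell_seed",
    "run_scenario_grid",
    "monthly_means",
    "decade_contrast",
]


@dataclass(frozen=True)
class ScenarioGrid:
    """Labels and replication of the factorial experiment."""

    models: tuple[str, ...] = climate_synth.MODELS
    sites: tuple[str, ...] = climate_synth.SITES
    decades: tuple[str, ...] = climate_synth.DECADES
    years_per_decade: int = 10
    base_seed: int = 0
    paired_seeds: bool = False  # share weather noise across decades

    @property
    def n_cells(self) -> int:
        return (
            len(self.models) * len(self.sites) * len(self.decades) * self.years_per_decade
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Everything computed for one grid cell (model, site, decade, year)."""

    model: str
    site: str
    decade: str
    year: int
    seed: int
    weather: tuple[WeatherDay, ...]
    consumption: SeasonConsumption
    trajectory: BiomassTrajectory
    final_biomass: float
    season_sum_biomass: float
    peak_day: int


def cell_seed(
    base_seed: int, model: str, site: str, decade: str, year: int,
    paired: bool = False,
) -> int:
    """Deterministic per-cell seed from the base seed and cell labels.

    In paired mode the decade label is omitted so the two decades of a
    site/model/year share their weather noise and differ only by the
    configured climate offsets.
    """
    label = f"{model}|{site}|{'' if paired else decade}|{year}"
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    entropy = int.from_bytes(digest, "big")
    seq = np.random.SeedSequence([base_seed, entropy])
    return int(seq.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_scenario_grid(
    grid: ScenarioGrid,
    run_config: SalmonRunConfig | None = None,
    eagle_model: EagleModel | None = None,
    decay_model: DecayModel | None = None,
) -> list[ScenarioResult]:
    """Run both simulations for every grid cell.

    The decay model defaults to the OLS fit of the shipped decomposition
    observations; the salmon run and eagle model default to their documented
    defaults. Identical base seeds reproduce identical output bit for bit.
    """
    if run_config is None:
        run_config = SalmonRunConfig()
    if eagle_model is None:
        eagle_model = EagleModel()
    if decay_model is None:
        decay_model = fit_decay_temperature_model(load_decay_observations())

    results: list[ScenarioResult] = []
    for model in grid.models:
        for site in grid.sites:
            for decade in grid.decades:
                for year in range(grid.years_per_decade):
                    seed = cell_seed(
                        grid.base_seed, model, site, decade, year, grid.paired_seeds
                    )
                    try:
                        scenario = climate_synth.make_scenario(site, decade, model)
                        weather = generate_winter_weather(scenario, seed=seed)
                        temps = daily_mean_temperatures(weather)
                        traj = simulate_carcass_biomass(
                            run_config, temps, decay_model,
                            dates=tuple(d.date for d in weather),
                        )
                        consumption = season_consumption(eagle_model, weather)
                    except ValueError as exc:
                        raise ValueError(
                            f"cell model={model} site={site} decade={decade} "
                            f"year={year}: {exc}"
                        ) from exc
                    summ = seasonal_summary(traj)
                    results.append(
                        ScenarioResult(
                            model=model,
                            site=site,
                            decade=decade,
                            year=year,
                            seed=seed,
                            weather=tuple(weather),
                            consumption=consumption,
                            trajectory=traj,
                            final_biomass=summ.final_biomass,
                            season_sum_biomass=summ.season_sum,
                            peak_day=summ.peak_day,
                        )
                    )
    return results


def monthly_means(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy long-format table of per-month means for each grid cell.

    Variables: daylight-weighted mean air temperature (°C), daily
    precipitation (mm), and daily eagle energy consumption (kJ). One row per
    cell × month × variable, ready for ANOVA in any statistics package.
    """
    rows = []
    for res in results:
        frame = pd.DataFrame(
            {
                "month": [d.date.strftime("%b") for d in res.weather],
                "temperature_C": [d.t_mean for d in res.weather],
                "precip_mm": [d.precip for d in res.weather],
                "consumption_kJ": [c.c_energy for c in res.consumption.daily],
            }
        )
        for month, grp in frame.groupby("month", sort=False):
            for variable, column in (
                ("temperature", "temperature_C"),
                ("precipitation", "precip_mm"),
                ("consumption", "consumption_kJ"),
            ):
                rows.append(
                    {
                        "model": res.model,
                        "site": res.site,
                        "decade": res.decade,
                        "year": res.year,
                        "month": month,
                        "variable": variable,
                        "value": float(grp[column].mean()),
                    }
                )
    return pd.DataFrame(rows)


def decade_contrast(
    results: list[ScenarioResult],
    past: str = "1970s",
    future: str = "2050s",
    reference_site: str = "HammaHamma",
) -> dict[str, pd.DataFrame]:
    """Decade contrasts per site × model, plus reference-site proportions.

    ``contrasts``: percent change ``100·(past − future)/past`` of the
    decade-mean seasonal consumption, final-day biomass, and season-summed
    biomass (positive = less in the future decade). ``proportions``: mean
    final biomass per cell relative to the reference site within each
    model × decade block.
    """
    frame = pd.DataFrame(
        {
            "model": [r.model for r in results],
            "site": [r.site for r in results],
            "decade": [r.decade for r in results],
            "consumption_kJ": [r.consumption.total_kj for r in results],
            "final_biomass": [r.final_biomass for r in results],
            "season_sum_biomass": [r.season_sum_biomass for r in results],
        }
    )
    means = (
        frame.groupby(["model", "site", "decade"], sort=False)
        .mean(numeric_only=True)
        .reset_index()
    )

    rows = []
    for (model, site), grp in means.groupby(["model", "site"], sort=False):
        by_decade = grp.set_index("decade")
        if past not in by_decade.index or future not in by_decade.index:
            raise ValueError(
                f"both decades required for model={model} site={site}"
            )
        for metric in ("consumption_kJ", "final_biomass", "season_sum_biomass"):
            p = by_decade.loc[past, metric]
            f = by_decade.loc[future, metric]
            if p == 0:
                raise ValueError(f"zero past-decade baseline for {metric}")
            rows.append(
                {
                    "model": model,
                    "site": site,
                    "metric": metric,
                    "pct_change": 100.0 * (p - f) / p,
                }
            )
    contrasts = pd.DataFrame(rows)

    prop_rows = []
    for (model, dec), grp in means.groupby(["model", "decade"], sort=False):
        ref = grp.loc[grp["site"] == reference_site, "final_biomass"]
        if ref.empty:
            raise ValueError(f"reference site {reference_site!r} missing from grid")
        ref_val = float(ref.iloc[0])
        for _, row in grp.iterrows():
            prop_rows.append(
                {
                    "model": model,
                    "decade": dec,
                    "site": row["site"],
                    "final_biomass": row["final_biomass"],
                    "proportion": row["final_biomass"] / ref_val,
                }
            )
    proportions = pd.DataFrame(prop_rows)
    return {"contrasts": contrasts, "proportions": proportions}
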