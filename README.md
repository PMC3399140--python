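# eaglewinter

Climate-driven winter bioenergetics of bald eagles (*Haliaeetus
leucocephalus*) feeding on chum salmon (*Oncorhynchus keta*) carcasses in
Puget Sound rivers.

Overwintering bald eagles congregate on rivers where post-spawning chum
salmon carcasses are the main winter food. Warming winters act on both sides
of that ledger: milder weather slightly lowers an eagle's daily energy
demand, while higher temperatures accelerate the decomposition of the
carcass pool and so shrink the food supply. `eaglewinter` is a tested,
seeded simulation pipeline for quantifying that contrast between decades,
rivers, and climate-model analogs. It is aimed at ecologists exploring
climate sensitivity of scavenger food webs who need a transparent,
reproducible forward model rather than access to the original downscaled
climate fields.

## The models

**Carcass decomposition.** Dry mass decays exponentially with a daily rate
constant estimated from paired mass measurements,

    k = ln(W_t / W_0) / t      (day⁻¹, negative for mass loss)

A pooled ordinary-least-squares regression of nine published salmonid
observations (−0.5 °C to 16 °C, shipped with the package) gives the
temperature dependence

    k(T) = −0.0032·T − 0.0072     (r² = 0.80, n = 9)

clamped at zero so cold weather can stop, but never reverse, decay.

**Salmon run.** A run of 40,560 chum salmon (3.652 kg wet, 16% dry matter)
enters from December 1 over ten weeks with truncated-normal timing, spends
10 days on the spawning grounds, then dies into the carcass pool. Each
death-day cohort decays daily at k(T) driven by the daylight-weighted mean
air temperature, and total dry biomass is summed through February 28.

**Eagle bioenergetics.** A 4.5-kg eagle holds constant mass by eating enough
carcass each day to cover its expenditure. Mass-specific expenditure is an
activity-weighted sum over behavioural states — gravel-bar feeding, daytime
perching, nighttime roosting, flapping and gliding flight (12.5× and 3.5×
basal rate) — with metabolic heat in each state rising linearly with cold
below the lower critical temperature, wind, precipitation, and the downward
longwave radiation deficit. Grams of food follow by dividing by the diet's
metabolizable energy density (3.764 kJ g⁻¹ wet mass).

**Synthetic climate.** Seeded 90-day winters (Dec 1–Feb 28) with AR(1)
persistent temperature anomalies, decade warming offsets concentrated in
January–February, intermittent gamma precipitation, Weibull winds, and a
bulk emissivity longwave model, partitioned into day and night by
astronomical photoperiod. Presets cover three rivers (Skagit, Hamma Hamma,
Nisqually) × two decades (1970s, 2050s) × two climate-model analogs.

## Worked example

```python
import eaglewinter as ew

decay = ew.fit_decay_temperature_model(ew.load_decay_observations())

past = ew.make_scenario("Skagit", "1970s", "A")
future = ew.make_scenario("Skagit", "2050s", "A")
w_past = ew.generate_winter_weather(past, seed=42)
w_future = ew.generate_winter_weather(future, seed=42)

cfg = ew.SalmonRunConfig()
traj_past = ew.simulate_carcass_biomass(cfg, ew.daily_mean_temperatures(w_past), decay)
traj_future = ew.simulate_carcass_biomass(cfg, ew.daily_mean_temperatures(w_future), decay)
print(ew.compare_decades(traj_past, traj_future))

eagle = ew.EagleModel()
print(ew.season_consumption(eagle, w_past).carcass_equivalents)
```

Output for this seed:

```
decay rate model: k = -0.0032*T + -0.0072  (r2=0.80, n=9)
final biomass 1970s: 9,742 kg dry
final biomass 2050s: 7,008 kg dry
season-summed biomass reduction: 13.5%
eagle winter demand 1970s: 134,892 kJ = 35.8 kg = 9.8 carcasses
demand decline under warming: 2.4%
```

Read: on the Skagit under model analog A, the same winter weather noise
warmed to 2050s offsets leaves 13.5% less carcass biomass integrated over
the winter, while the eagle's own energy demand falls only 2.4% — the
food-supply effect dominates the demand effect by a wide margin. One eagle's
winter demand is roughly ten carcass-equivalents.

The same steps are available from a shell:

```sh
eaglewinter generate-weather --seed 42 --out weather.csv
eaglewinter fit-decay --out decay.yaml
eaglewinter simulate-carcasses --weather weather.csv --out trajectory.csv
eaglewinter eagle-demand --weather weather.csv --out demand.csv
eaglewinter run-grid --seed 1 --outdir grid/     # full 120-cell factorial
```

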