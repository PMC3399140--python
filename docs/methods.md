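# Methods

## Scope and structure

The package couples three forward models — a synthetic winter-climate
generator, a temperature-driven carcass-decomposition simulation, and a
daily eagle bioenergetics model — under a factorial scenario pipeline
(climate-model analog × river × decade × replicate winter). The climate
generator emulates the statistical structure of downscaled regional-climate
output; it does not ingest or re-run any atmospheric model. Routine
inferential statistics (ANOVA, post-hoc tests) are deliberately out of
scope: the pipeline's contract is to emit tidy per-month tables
(`monthly_means`) that any statistics package can consume.

## Winter definition and photoperiod

Winter is December 1 through February 28: 90 days, with February 29 never
emitted even in leap years, so that trajectories from different decades
align day-for-day. Day length is the astronomical formula from solar
declination and the sunset hour angle at a 90.833° zenith (solar-disk radius
plus standard atmospheric refraction), which matches conventional
solar-geometry calculators to within a few minutes at mid-latitudes.
Latitudes are restricted to (0°, 66°) N; poleward of that the winter sun may
never rise and the formula is undefined. Day length is used twice: to split
each day's weather into day and night phases, and to set the eagle's
nightly roosting fraction.

## Synthetic climate generator

Daily mean temperature is `winter mean + month offset + AR(1) anomaly`. The
anomaly process is stationary with standard deviation 3 °C and lag-1
coefficient 0.7 — enough persistence to mimic multi-day synoptic spells
without modelling weather fronts. The day/night split adds
`Δ·(1 − daylight/24)` to the mean by day and subtracts `Δ·(daylight/24)` by
night (Δ = 2 °C), which conserves the daylight-weighted daily mean exactly.
Precipitation is a Bernoulli wet-day indicator times a gamma amount; wind is
Weibull (shape 1.8, scale 3.5 m s⁻¹) drawn separately for day and night;
downward longwave is `ε_eff·σ·T_K⁴` with
`ε_eff = ε_clear + Δε·cloud_fraction` (0.70 + 0.20·cloud), cloudiness drawn
around a decade-specific mean (0.75 in the 1970s, 0.70 in the 2050s —
slightly clearer future winters) with a bump on wet days.

Random streams are consumed in a fixed order independent of the temperature
parameters, so two scenarios sharing a seed differ *exactly* by their
configured offsets — the basis of the paired-decade experiments.

Site presets place winter means at 5.0 °C (Nisqually), 4.0 °C (Skagit) and
3.0 °C (Hamma Hamma), reproducing the observed warmest-to-coldest ordering,
with Nisqually driest (wet-day probability 0.50, gamma scale 9 mm). Model
analog A runs 0.5 °C warmer and slightly drier than analog B, mirroring the
warm/dry-versus-cool/wet split between the two regional forcings the study
system is described with. Decade warming is +1.0 °C in December and +2.5 °C
in January and February — warming concentrated in late winter. No per-site
means or offsets are published numerically, so these preset magnitudes are
calibrated choices, fixed once and configurable; tests assert the orderings
and contrasts, not the absolute values. Latitudes (48.4, 47.55, 47.1° N)
are approximate river-mouth positions and matter only through photoperiod.

## Carcass decomposition

The decay rate is `k = ln(W_t/W_0)/t` (day⁻¹), stored negative for mass
loss. The shipped table of nine published salmonid observations spans
−0.5 °C to 16 °C in both air and water exposure; exposures are pooled in an
unweighted OLS of k on temperature (plain OLS reproduces the published
coefficients, slope −0.0032, intercept −0.0072, r² 0.80, so no hidden
weighting is assumed). Predictions are clamped at k ≤ 0: the fitted line
crosses zero near −2.25 °C and, unclamped, sub-freezing weather would make
carcasses gain mass. Air temperature drives the decay of the eagle-relevant
pool — carcasses pulled out of the water. Energy-density decline with
carcass age is not modelled, only dry mass.

## Salmon run

Defaults: 40,560 fish (the exact figure, in preference to the rounded
~41,000), 3.652 kg wet mass, 16% dry matter, first entry December 1, a
70-day run, 10-day spawning-grounds lifespan. Entry timing is a normal
distribution truncated to the run window; the mean (day 35) and SD (70/6,
so ±3 SD spans the run) are not published and are configurable. Fractional
daily entries are integerised by largest-remainder apportionment so the
total is exactly the run size — the run is treated deterministically. Deaths
are entries shifted by the lifespan; all cohorts dying the same day are
merged (they share every subsequent decay factor), keeping the simulation at
90 × 90 operations. A cohort enters the pool at full dry mass on its death
day and is multiplied by `e^{k(T)}` each subsequent day, with T the
daylight-weighted daily mean air temperature. Seasonal summaries report the
final-day (Feb 28) biomass, the season-summed daily biomass (kg·days) —
the operational reading of "winter carcass availability" used in decade
contrasts — and the peak-biomass day. Eagle consumption does not feed back
on the carcass pool; supply and demand are modelled independently.

## Eagle bioenergetics

The model balances energy at constant body mass: daily intake equals daily
expenditure. Mass-specific expenditure is

    E = f_gb·M_day(active) + f_p·M_day(rest) + f_r·M_night(rest)
        + f_af·12.5·BMR + f_pf·3.5·BMR        (kJ·kg⁻¹·day⁻¹)

where the f's are fractions of the 24-h day (roosting takes the whole
night, `f_r = 1 − daylight/24`; daylight is divided 0.35 gravel-bar
feeding, 0.55 perching, 0.04 flapping flight, 0.06 gliding flight — a
configurable placeholder, since no observed budget is published), and

    M = SMR(T, state) + c_w·wind + c_p·precip + c_L·max(0, σT_K⁴ − LW)

with resting SMR equal to BMR above the 10 °C lower critical temperature and
rising 4 kJ·kg⁻¹·day⁻¹ per °C below it, the active state twice resting,
and flight costs fixed BMR multiples that bypass the weather terms. The
longwave surcharge is proportional to the deficit of the incoming flux below
blackbody emission at air temperature, so radiatively colder (clearer) skies
cost energy. Food intake is `E·mass/WME` grams with WME = 3.764 kJ per gram
wet mass, and carcass-equivalents divide by a configurable 3,652 g edible
wet mass per carcass.

Defaults: BMR allometry 327.6·M^0.723 kJ·day⁻¹ (a standard nonpasserine
scaling; 216 kJ·kg⁻¹·day⁻¹ at 4.5 kg), c_w = 3.0 per m s⁻¹, c_p = 0.5 per
mm, c_L = 0.1 per W m⁻². These give mid-winter intakes of roughly
350–450 g·day⁻¹ (≈10 carcass-equivalents per winter), a plausible magnitude,
and satisfy the directional structure the model is used for: consumption
falls with temperature below t_lc (the 4 kJ cold slope dominates the
≈0.5 kJ·°C⁻¹ growth of the blackbody reference), rises with wind and
precipitation, falls with downward longwave. Above t_lc the temperature
monotonicity is not claimed. All constants are configuration, not code.

**Unit caveat.** The diet energy density is quoted in the source literature
as "3.764 kJ·kg⁻¹", which is dimensionally inconsistent with daily intakes
in grams at ~10³ kJ·day⁻¹ expenditure. It is interpreted here as kJ per
*gram* wet mass, which yields realistic few-hundred-gram daily intakes. The
exact algebra of the published consumption equation is not recoverable from
its text (it is printed as an image and its sub-model constants live in
earlier work); the activity-weighted energy balance above is this package's
documented reconstruction. Consequently the published "<1%" decade change in
demand and the "0.1–0.2 carcasses" conversion are treated as directional
properties, not numerical reproduction targets.

## Scenario pipeline and seeding

The default grid is 2 model analogs × 3 sites × 2 decades × 10 winters =
120 simulations. Each cell's seed is a 31-bit value derived from the base
seed and a blake2b hash of the cell labels via numpy's `SeedSequence` —
cells are mutually independent yet the whole grid reruns bit-identically
from one integer. A paired-seed mode omits the decade from the hash so both
decades of a site/model/year share weather noise (the contrast then isolates
the configured offsets); the default is independent draws, since it is not
known whether the original decade draws were paired. `monthly_means` emits
the 360-row-per-variable tidy table (120 cells × 3 months: 31/31/28-day
months); `decade_contrast` reports `100·(past − future)/past` per
site × model and final-biomass proportions relative to the Hamma Hamma cell
within each model × decade block.

## What the synthetic generator does and does not establish

The generator reproduces the *structure* the analysis needs — site and
decade mean contrasts, day-to-day persistence, realistic marginal
distributions, weather–cloud covariation — but not spatial correlation
between sites, within-day (hourly) structure, snow/rain partitioning, or any
actual downscaled field. Tests passing under it therefore validate the
decay, run, bioenergetics and pipeline machinery and the direction and
rough magnitude of decade contrasts; they do not validate the original
climate projections themselves. The +2.5 °C uniform-warming experiment
(mean 5 °C baseline, 20 seeds) lands a 13–14% season-summed biomass
reduction, consistent with the 11–14% range reported for the real
downscaled series.

## Numerical choices and degenerate inputs

- OLS fits with < 2 observations or zero temperature spread raise; r² is
  clipped to [0, 1] against floating-point overshoot on collinear input and
  set to 0 for constant-k input.
- Entry integerisation ties are broken by stable sort, making schedules
  reproducible; symmetry of the truncated-normal schedule holds to ±1 fish.
- A run of 0 fish yields an all-zero trajectory; decade comparison against a
  zero baseline raises rather than returning infinities.
- Biomass linearity in run size is exact per cohort but subject to ±1
  fish/day apportionment granularity (< 10⁻³ relative at default run sizes).
- Weather CSVs are validated row-by-row (negative precipitation, date gaps,
  non-numeric cells reported with their row number); empty files are an
  explicit error.
- Problem sizes throughout (90-day winters, 90 cohorts, 120-cell grid,
  20-replicate warming experiments, 1000-replicate convergence checks) run
  in seconds on one CPU.

## Known limitations

Constant eagle body mass and uniform diet; no demography, prey switching,
foraging-efficiency density dependence, or consumption feedback on the
carcass pool; no river-flow effects on carcass availability; decay responds
to temperature only, not carcass size, sunlight, or scavenger assemblage;
preset climate magnitudes are calibrated, not fitted to observations.
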