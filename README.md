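# paleopop

Climatic limiting-factor hindcasting of hunter-gatherer population density.

## The problem

Forager populations grow by default; what needs explaining is what *stopped*
them. By Liebig's law of the minimum, at any place and time the scarcest
requirement — not the average of all requirements — caps population size.
This package identifies, per grid cell and 500-year time step across a
glacial–interglacial transition, which climatic variable imposed the lowest
ceiling on hunter-gatherer population density, and what that ceiling was.

It is written for quantitative palaeoecologists and archaeologists: the
library (`src/paleopop`) holds every computation, the numbered scripts under
`analysis/` run the study pipeline on a synthetic world with known ground
truth, and the same code ingests real inputs (ethnographic CSV, CF-style
NetCDF climate cubes) when you have them.

## The method

1. **Calibration.** From an ethnographic table of mobile, terrestrially
   oriented foragers (food producers, sedentary, aquatic-reliant and
   equestrian societies filtered out), ten bioclimatic predictors are
   derived per society from monthly temperature and precipitation:
   ET, PET, NPP, MCM, MWM, TS, TAP, PDM, PWM, PSeason.
2. **Quantile regression.** For each predictor x separately, and for
   τ ∈ {0.1, 0.5, 0.9}, a penalized-spline quantile model f̂_τ of
   y = log₁₀ density is fitted by minimising

       Σᵢ ρ_τ(yᵢ − f(xᵢ)) + λ‖Δ²c‖²,   ρ_τ(u) = u·(τ − 1{u<0}),

   with f a cubic P-spline with coefficients c and λ chosen by
   cross-validated pinball loss. Each model is refitted over spatially
   blocked folds (h-block: training records within h km of any test record
   are dropped) to defeat spatial autocorrelation, h = 4500 km by default
   (the variogram range of the calibration density field).
3. **Hindcast.** Ensembles are projected cell-wise onto a paleoclimate cube
   after a non-analogy screen (variables outside their calibration domain
   are dropped per step). Per cell, density D̂ = min over variables of the
   fold-mean 10^f̂, and the limiting factor is the argmin; cells with
   D̂ > 0.2 persons/100 km² are occupied; population size is
   Σ D̂/100 × cell area over occupied ice-free cells, with 95% bands from
   fold percentiles.
4. **Validation.** The population series is correlated against a
   radiocarbon date-count proxy binned to millennia.

The synthetic-data generator (`paleopop.synth`) is first-class, tested code:
it produces a forager table whose conditional density quantiles follow known
response curves, a paleoclimate cube with interstadial/stadial events and a
shrinking ice mask, and a radiocarbon table tracking a known population
curve — so parameter recovery can be measured exactly. See
`docs/methods.md` for the model, numerics and the generator's scope.

## Worked example

Run the pipeline on the seeded synthetic world (about a minute in total):

```sh
python analysis/01_simulate_world.py
python analysis/02_derive_predictors.py
python analysis/03_fit_quantile_models.py
python analysis/04_hindcast_density.py
python analysis/05_summaries_validation.py
```

Outputs land under `results/`. The run prints, among other things:

```
Filters: 340 societies -> 163 foragers (food producers 85, sedentary 34,
  aquatic 41, equestrian 17)

variable   tau  deviance_explained_mean  r2_test_mean
      ET 0.500                    0.446         0.739

Median (tau=0.5) hindcast:
  21.0 kyBP: population 39,209 [23,954, 49,341], occupied fraction 0.91
   8.0 kyBP: population 270,424 [218,029, 312,630], occupied fraction 1.00

Limiting factors at 21 kyBP (share of ice-free area): ET 100%
Limiting factors at 8 kyBP (share of ice-free area): ET 70%, TS 18%, TAP 12%

Radiocarbon proxy: Pearson rho = 0.99, p = 7.9e-11 over 14 millennium bins
```

Reading this: after filtering, 163 societies calibrate the models; effective
temperature is the strongest single predictor of median density (held-out
deviance explained 0.45). The hindcast population grows roughly sevenfold
across deglaciation with the occupied fraction of ice-free land expanding;
energy (ET) limits the whole glacial continent, while by the early
interglacial a regional mosaic emerges where seasonality (TS) and annual
precipitation (TAP) cap density in continental and arid regions. The date
proxy tracks the hindcast closely — on the synthetic world both derive from
the same truth, so this checks internal consistency, not archaeology.

The same stages are exposed as a CLI (`paleopop simulate|derive|fit|
hindcast|summarize|validate|run-all --config cfg.yml`), with every run
writing a provenance sidecar (config hash, seeds, versions).

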