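# Methods

## The model

The package estimates where and when individual climatic variables capped
hunter-gatherer population density, following Liebig's law of the minimum:
at any place and time the scarcest requirement, not the average of all
requirements, limits population size.

The chain has four stages.

1. **Calibration.** An ethnographic table of mobile, terrestrially oriented
   forager societies supplies observed population densities (persons/100 km²,
   log10-transformed) and monthly climates. Ten bioclimatic predictors are
   derived per society: effective temperature (ET), Thornthwaite potential
   evapotranspiration (PET), Miami-model net primary productivity (NPP),
   coldest/warmest-month means (MCM/MWM), temperature seasonality (TS,
   population sd of monthly means), log10 annual precipitation (TAP), log10
   driest/wettest-month precipitation (PDM/PWM), and precipitation
   seasonality (PSeason, percent CV of monthly totals).
2. **Quantile smoothing.** For each predictor separately, a τ-quantile
   penalized spline of log10 density is fitted for τ ∈ {0.1, 0.5, 0.9} —
   minimum, typical and maximum density responses. Models are univariate by
   design: the question is the absolute ceiling each variable imposes, not
   the relative contribution of correlated predictors.
3. **Hindcasting.** Each fitted ensemble is projected cell-wise onto the
   derived predictor fields of a gridded monthly paleoclimate cube
   (500-year steps). The per-cell density is the minimum across retained
   variables; the argmin variable is the limiting factor. Cells with density
   strictly above d_min = 0.2 persons/100 km² (the lowest calibration
   density) count as occupied, and continental population size is
   Σ density/100 × cell area over occupied ice-free cells.
4. **Validation.** The population time series is compared (Pearson
   correlation over 1000-year bins, 21–10 kyBP window) against a
   radiocarbon date-count proxy.

## The quantile smoother

f_τ minimises Σᵢ ρ_τ(yᵢ − f(xᵢ)) + λ‖Δ²c‖², where ρ_τ is the pinball loss,
f = Σ c_j B_j a cubic B-spline expansion (default 10 basis functions) on
*equally spaced* knots extending beyond the data range (a P-spline), and Δ²
the second-difference penalty. Equally spaced knots make the penalty null
space contain straight lines exactly, so λ → ∞ degenerates to linear
τ-quantile regression (tested against a linear-programming oracle).

Numerics: the pinball loss is smoothed with ε = 1e-6·sd(y) (configurable)
and minimised by asymmetric iteratively-reweighted least squares with
weights |τ − 1{r<0}|/max(|r|, ε); each iteration is one small penalized
normal-equation solve. Convergence is declared when coefficients or the
objective stop moving (relative 1e-8); divergence (non-finite iterates)
raises. λ is selected by 5-fold random cross-validation of held-out pinball
loss over a 20-point log grid spanning 1e-4…1e4.

Quantile curves are fitted independently per τ; crossing is therefore
possible, is measured by `crossing_rate`, and is reported rather than
repaired (< 2% of evaluation points on the synthetic calibration data).

## h-block cross-validation

Forager societies are spatially (and culturally) autocorrelated, so random
train/test splits leak. Each of the ensemble folds is a random 70/30 split
from which every training record within h km of any test record is dropped
("buffered" strategy, the standard h-block construction). A "literal"
strategy — greedily thinning the training set to pairwise ≥ h spacing — is
also implemented, because the archival description is ambiguous; it is far
more aggressive and usually leaves too few records to fit, which is why
buffered is the default. Folds whose training set falls below 30 records
are re-drawn (bounded retries), and per-fold exclusion counts are logged.

h defaults to 4500 km, the variogram range of the archival calibration
table, so the variogram fit is optional; `empirical_variogram` (Matheron
estimator, WLS spherical fit) supports estimating it instead. On the
synthetic world the drivers use h = 1200 km, matched to the generator's
~8° spatial correlation length — the synthetic analogue of taking h from
the spatial dependence of the data. (The raw variogram range of the
synthetic table is dominated by the planetary latitudinal trend rather than
the residual field, which is why the drivers do not take it literally.)

Ensemble metrics are the across-fold mean and percentile 95% interval
(2.5%/97.5%) of held-out deviance explained — 1 − pinball(fit)/pinball
(empirical τ-quantile), the quantile analogue of unadjusted R² — and of the
squared Pearson correlation between predicted and observed values. The
correlation is reported for both the held-out and the training set, since
the archival summary is ambiguous about which it used. λ is selected once
per (variable, τ) on the full filtered table and reused across folds
(default "shared" mode): fold-wise re-selection multiplies runtime ~100×
and adds selection noise without changing the fitted curves appreciably;
"per_fold" mode remains available.

## Non-analogy screen and projection

A model fitted on present-day climates cannot be trusted outside its
calibration domain. Before projection, each variable is screened per time
step. The default "variable" policy retains a variable only while its
continental ice-free area-weighted mean lies inside the ensemble's pooled
training range — dropping a variable wholesale for the affected steps, the
coarse-grained reading under which the warmest-month variable is excluded
in the archival analysis. The "cell" policy instead masks out-of-range
cells per variable. Both are implemented because the archival phrasing
("all historical means were contained under current conditions") admits
either reading; the choice is logged per step. Within retained variables,
fold curves are evaluated with *clamped* (constant) extrapolation beyond
the training range — never spline extrapolation — and `predict` always
flags out-of-domain points.

Fold predictions are averaged on the linear density scale (mean of 10^ŷ),
matching an average of density predictions; log-scale averaging is
available behind a flag. Linear-scale averaging inflates central densities
slightly when folds disagree (Jensen), which is visible in the synthetic
world as occupied fractions reaching the threshold earlier than the truth.
Bands are fold percentiles (2.5/97.5); the limiting factor is the per-cell
*mode* of the per-fold Liebig argmins. Argmin and mode ties break by the
fixed variable order (ET, PET, NPP, MCM, MWM, TS, TAP, PDM, PWM, PSeason)
and are flagged, never silent.

## Predictor conventions

* ET = (18·MWM − 10·MCM)/(MWM − MCM + 8) °C; defined whenever MWM ≥ MCM.
* PET: Thornthwaite monthly formulation with the standard day-length ×
  month-length correction (hot-month quadratic branch above 26.5 °C; months
  at/below 0 °C contribute nothing). The method sits behind a single
  configurable interface because different PET conventions circulate. Note
  PET is the only predictor that is not a symmetric function of the twelve
  monthly values: its correction is month-labelled by construction.
* NPP: Miami model, min(3000/(1+e^{1.315−0.119T}), 3000(1−e^{−0.000664P}))
  with a configurable dry-matter→carbon factor (default 1.0, i.e. the
  classic 3000 g·m⁻²·yr⁻¹ ceiling; 0.45–0.5 for strict carbon units).
* TS is the population (divisor-12) sd in plain °C, not the ×100 dialect;
  PSeason is 100·sd/mean of monthly totals.
* Precipitation logs are log10(x + 1 mm) so dry months are admissible; the
  offset can be disabled.
* Mean annual temperature for NPP is the mean of the 12 monthly means.

Cell areas use the spherical band formula R²·Δλ·(sin φ_top − sin φ_bottom),
R = 6371 km (a 0.5° cell at the equator is ≈ 3091 km²; a global grid sums
to 4πR² to 1e-6 relative).

## The synthetic world

The generator emulates the *shape* of the archival inputs with known ground
truth; it does not imitate any real geography or climate-model physics.

* **Responses.** Ground truth is a set of per-predictor median curves μ_v
  with heteroscedastic spread σ·s_v(x). A record's log10 density is
  m + σ·s(x*)·Z with m = min_v μ_v(x_v) (Liebig applied to the generative
  curves), x* the limiting variable, Z standard normal. Conditional
  quantiles are exactly m + σ·s·z_τ: calibrated by construction,
  non-crossing, and degenerate to the median curve at σ = 0. Defaults: ET
  rising steeply from log-density ≈ −1.5 in cold climates, TS falling with
  seasonality, TAP rising with annual precipitation, with curve amplitudes
  chosen so each variable is decisively limiting in a distinct climatic
  regime (cold / continental / arid) — the regime margins exceed the
  smoother's estimation error, which is what makes limiting-factor
  recovery a meaningful target. Base noise σ = 0.25 log10 units, a
  realistic ethnographic scatter.
* **Ethnographic table.** 340 societies (≈160 after filtering, matching the
  scale of the archival table) scattered globally; monthly climates are a
  latitudinal baseline plus spatially correlated anomalies (truncated
  cosine-basis Gaussian fields, correlation length 8°) plus independent
  jitter. Seasonal amplitude and wetness vary strongly and independently of
  the thermal gradient so the three responses are separately identifiable.
  Configurable fractions carry excludable metadata (25% food producers, 10%
  sedentary, 12% aquatic-reliant, 5% equestrian), assigned independently of
  climate.
* **Paleoclimate cube.** 1° grid (36×60, a Europe-sized window; coarser
  than the archival 0.5° for desk-scale runtime), 21.0→8.0 kyBP in 0.5 ky
  steps. Temperatures carry a 15 °C secular glacial-to-interglacial warming,
  a +3 °C interstadial pulse at 14.7 kyBP and a −4 °C stadial pulse near
  12.7–11.7 kyBP; seasonal amplitude grows eastwards (continentality);
  precipitation scales mildly with warming. The spatial random fields are
  fixed in time, so the event-free trend is strictly monotone. The ice mask
  thresholds a fixed potential with a monotonically rising threshold: cover
  can only recede.
* **Radiocarbon table.** Poisson date counts per millennium proportional to
  a supplied population curve (default 0.002 dates/person), with uniform
  ages within bins. No calibration-curve structure is modelled, matching
  the count-based use of the proxy.
* Everything is reproducible from one integer seed; the cube is a single
  realization per seed (the archival forcing likewise carries no
  uncertainty estimate).

**What passing on this world does and does not show.** It shows the
pipeline's statistics are correct and well-calibrated: quantile coverage,
the h-block contract, exact Liebig/occupancy/population accounting, ≥90%
limiting-factor recovery and rank-correlation ≈1 of the population
trajectory when regimes are decisively separated. It does not validate the
ecological claims on real data: real predictors are far more collinear than
the generator's (which deliberately decorrelates them), real coastlines and
orography structure climate differently, and archival density estimates
carry reporting error the generator does not model. The archival headline
numbers are reproducible only with the archival inputs.

## Degenerate inputs and edge rules

* Occupancy is strict (> d_min), so a cell at exactly 0.2 persons/100 km²
  is unoccupied.
* Radiocarbon binning is half-up (10 500 BP → 11 000).
* A fold whose buffered training set empties errors after bounded retries;
  an ensemble with under half its folds successful errors.
* A time step at which the screen excludes every variable errors: there is
  no basis for prediction.
* Constant response (null pinball loss 0) defines deviance explained as 0.
* Variogram bins with fewer than 5 pairs are dropped; fewer than 3 usable
  bins refuses the fit.

## Known limitations

* The smoother's ε-smoothed IRLS is a fixed-point scheme, not an exact LP
  solve; agreement with LP oracles is ~1e-7 on clean data but only the
  documented tolerances are guaranteed.
* Single-realization climate forcing: no forcing uncertainty propagates
  into the bands (they reflect calibration sampling only).
* Linear-scale fold averaging biases central densities high where folds
  disagree (documented above); the log-scale flag exists for sensitivity
  analysis.
* The variogram range of a single spatial realization is a high-variance
  estimate; recovery within ±20% holds at the tested conditions, not for
  every realization.
* Southern-hemisphere synthetic societies reuse the northern seasonal
  phase; all predictors except PET are phase-invariant, so only PET is
  mildly affected.
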