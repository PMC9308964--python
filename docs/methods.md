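# Methods

## Conditional-quantile view of storage potential

The package treats SOC concentration at a location as a conditional
distribution given climate (MAT, TAP), elevation and land cover. The median
of that distribution is read as the *current state* under common practice;
upper percentiles describe comparable locations that hold more carbon, and
the gap q75 − q50 (intermediate) or q90 − q50 (technical maximum) is the
additional storage potential. This is an observational, not mechanistic,
notion of potential: it assumes the covariates capture the non-management
drivers, so that vertical spread at fixed covariates is mostly management.

## Quantile network

A single fully-connected trunk (default three hidden layers of 20 ReLU
units) feeds five linear heads, one per percentile (0.25, 0.50, 0.75, 0.90,
0.95). Heads minimize the pinball loss; the training objective is the sum of
the five batch-mean head losses. The 25th and 95th heads act as co-trained
regularizers and are never consumed downstream. Implementation is plain
numpy (forward, backprop, Adam) — the problem is small and this keeps the
entire train/predict path deterministic under a single seed.

Numerical choices:

* **Quantile crossing** — head outputs are sorted per location after
  prediction; occurrences are counted and logged. Negative predictions are
  floored at 0 % SOC (physical bound).
* **Subgradient at zero residual** — the pinball derivative uses the
  (τ − 1) branch at exactly zero residual; with continuous data, ties have
  measure zero.
* **Standardization** — continuous covariates are z-scored with mean/sd
  estimated on training rows only; land cover enters as a 3-class one-hot
  block in the pooled model. Per-land-cover models (no land-cover covariate)
  are supported as an alternative mode; the pooled model is the default
  because the debt scenario needs counterfactual land-cover substitution.
* **Data splitting** — a simple random test hold-out (default 5 %), then
  bootstrap resamples of the pool: the resample trains, the out-of-bag rows
  (≈ e⁻¹ of the pool) validate; model selection across resamples takes the
  lowest out-of-bag total loss, ties broken by seed order.

Training defaults are 100 epochs, batch 32, learning rate 0.001 (Adam).
The package's synthetic studies use a longer schedule,
`SYNTHETIC_STUDY_TRAINING` (200 epochs, batch 128, lr 0.003 decaying
exponentially to 3 % of its initial value): on the 6-covariate synthetic
problem the constant-rate schedule leaves the heads hovering around the
optimum, and the decayed schedule converges held-out coverage to within
0.01 of nominal for all five percentiles.

## Equal-area spline

Profiles report SOC over arbitrary depth intervals; harmonization fits a
continuous, continuously differentiable piecewise-quadratic f(d) minimizing

    (1/n) Σ_i (mean of f over layer i − y_i)² + λ ∫ f′(d)² dd

and returns the mean of f over 0–30 cm. The minimizer of this functional
over all square-integrable-derivative functions is piecewise quadratic on
the layer partition (the stationarity condition makes f″ piecewise
constant), so the fit is computed exactly by solving the KKT system of the
equality-constrained quadratic program in the 3 coefficients per piece.
Gaps between measured layers become penalty-only pieces. A vanishing
Tikhonov term (1e-12 on the roughness) selects the smoothest minimizer in
degenerate cases (λ = 0, single layer).

Choices the data sources do not dictate: λ defaults to 0.1 (the
conventional value); profiles whose measured support stops short of 20 cm
are dropped from 0–30 cm standardization; support reaching 20 cm but not
30 cm is extended as a constant anchored at the fitted value in the deepest
layer's midpoint. Depth intervals are half-open [top, bottom) cm measured
downward.

## Bulk-density pedotransfer

BD(oc) = (a − b·oc)/(c·oc + d) with the published global coefficients
(83.2687, 0.011, 0.635, 52.847; oc in g kg⁻¹) as default. The form is
invariant to scaling all four coefficients, so `fit_ptf` optimizes with
d fixed at 1 (Levenberg–Marquardt via `scipy.optimize.least_squares`,
seeded jitter restarts on failure) and returns that normalized
representative; diagnostics report RMSE and mean bias. Percent-to-g kg⁻¹
conversion (×10) happens at the module boundary. In stock accounting BD is
re-evaluated at each percentile's own concentration — organic matter is
light, so upper-percentile stocks grow less than upper-percentile
concentrations; a `fixed_bd` switch enables constant-BD sensitivity runs.

## Stocks and scenarios

Stock = (oc %/100) · BD·1000 · 0.3 m in kg C m⁻²; zone totals multiply by
the explicit per-cell area layer (kg m⁻² × km² × 10⁻⁶ = Pg). Zone totals
are additive by construction and monotone across percentiles after
non-crossing enforcement. Equivalent-soil-mass corrections are not applied:
stocks are fixed-depth 0–30 cm.

The 4‰ scenario assumes linear accumulation of rate × baseline stock per
year, so years = (s_t/s₀ − 1)/rate, reported per cell with median/quartile
summaries; negative potentials map to 0 years and are counted. The average
capture rate divides a total added stock by a timeline (for the published
arithmetic: the potential by the printed median years, which reproduces the
printed 0.34 Pg C yr⁻¹; the alternative rate × global stock path is also
computed). Historical debt substitutes the land cover of cropland cells
(pasture/natural at q50, forest at q90) and totals the signed per-cell
stock differences by default; per-cell positive-part clipping is a flag.
Climate projection re-predicts with replaced MAT/TAP layers on identical
geometry and reports percent change of the q50 stock and both potentials;
ensemble averaging across climate models is the caller's responsibility.

## Sampled Shapley attribution

Permutation-sampling estimator: for each sampled feature ordering, a
background row supplies unrevealed features, and the prediction change when
a feature's value switches from background to instance is credited to that
feature; averaging over orderings (default 200) converges to the exact
Shapley value and preserves local accuracy in expectation. Land cover moves
as one feature (its one-hot block switches together). Percent change of
mean |contribution| between percentile heads normalizes for higher heads
predicting larger values. Defaults: 200 permutations, 100-row seeded
background subsample.

## Synthetic data: what it emulates, what it does not

The generator emulates the *structure* the method assumes: SOC lognormal
conditional on covariates (right-skewed, heteroscedastic in the class-wise
option), location linear in standardized covariates (SOC falling with
temperature, rising with rainfall and elevation) plus additive land-cover
offsets with pasture/natural (+0.28) and forest (+0.40) above cropland;
σ_log = 0.5 gives q90/q50 ≈ 1.9, matching the strong skew of field SOC
data; a baseline median of ~1.5 % SOC at mid-range climate is typical of
cropland topsoil. Profiles decay exponentially with depth, scaled so the
0–30 cm mean equals the site value exactly (a layer boundary is always
placed at 30 cm). Grids are smooth random surfaces with explicit per-cell
areas (0.25 km², a 500 m grid) — no geodesy.

Because every conditional quantile is closed-form, coverage and recovery
tests have analytic oracles. What passing them shows: the pipeline
recovers a known conditional distribution from samples of the size used.
What they cannot show: performance under real-world covariate error,
spatial autocorrelation, sampling bias toward agricultural regions, or a
misspecified conditional law — none of which the generator simulates.

## Problem sizes and tolerances

Synthetic studies use 20,000 sites × 3 seeds for coverage (±0.03 band),
5,000 pairs for pedotransfer recovery (noiseless curve within 1e-4 g cm⁻³;
RMSE within 15 % of the injected 0.25 g cm⁻³), 300 four-layer profiles for
harmonization recovery (median relative error < 5 %, observed ≈ 0.4 %),
and 2,000 permutations for Shapley-vs-enumeration agreement (within 5 % of
the largest exact value, local accuracy within a 3σ Monte-Carlo bound).
The spline is checked against an independent 1 mm dense-discretization QP
oracle at 1e-3. Published-arithmetic checks use the packaged ecoregion
table at the tolerances its own rounding implies (0.05 Pg on totals).

## Known limitations

* The accounting reproduces the published *arithmetic*; the headline global
  maps and their medians require the real observation database and rasters.
* The q90 recoup fraction computed from the packaged table (70.8 % of the
  92 Pg debt) differs from one published mention of 72 %, which traces to a
  differently-sourced q90 potential; both paths are reported, neither is
  adjudicated.
* Linear 4‰ accumulation is an idealization; saturating dynamics are out
  of scope.
* Attribution assumes feature independence in the background sample, as
  permutation Shapley does.
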