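# Methods

This note documents the models, defaults and numerical choices behind
`thermoguild`, and what the synthetic-data tests do and do not
establish about real tracking data.

## Synthetic world

The generator emulates a multi-year GPS study of a three-species
predator guild in a two-season system.

**Temperature.** Daily maxima follow a per-season mean plus a
within-season sinusoid (which integrates to zero over each season, so
the seasonal median equals the configured mean), plus an AR(1)
disturbance.  Defaults are calibrated to the study system: dry season
(May–October) mean 28.8 °C clamped to [16.8, 40.7]; wet season
(November–April) mean 31.1 °C clamped to [19.9, 42.1]; AR(1)
coefficient 0.65, innovation sd 3 °C, within-season amplitude 1 °C.
Clamping is enforced by rejection-resampling the innovation (up to 200
draws, then clipping), which preserves the autocorrelation structure
approximately; a long-run check shows the lag-1 autocorrelation of an
unclamped configuration is recovered within ±0.02.

**Habitat.** A nearest-nucleus tessellation of seeded patch centres
gives a patchy 4-class raster (grassland, floodplain, mixed woodland,
mopane) at 10 m resolution, with a mixed-woodland disc forced under
the shared zone.  I/O uses the ESRI ASCII grid format (plain text).

**Sun table.** Sunrise/sunset are a seasonal sinusoid (mean 06:15 /
18:24 UTC, ±30 min amplitude), not an astronomical model: only the
anchoring of the sun-time transform matters downstream.

**Movement.** Each agent is a two-state (rest/move) switching
correlated random walk: gamma step lengths, von Mises turns, an
optional diel modulation of the probability of starting to move, and
habitat preference applied by accept/reject on the step endpoint.  Two
heading biases are mixed into the CRW: a home-centre bias whose weight
grows with distance from the home centre (keeps ranges stationary),
and a **shared-zone bias** with weight
`logistic(base + slope * z(T_{d-1}))` — the programmed ground-truth
lag-1 temperature effect.  Scheduled fixes carry ±60 s uniform timing
jitter, specifically to exercise the 2.5 min concurrency matcher.
The CRW is an artifact of the generator, not a claim about how real
animals move; passing the end-to-end tests shows the *pipeline*
recovers programmed effects, not that real data meet the generator's
assumptions (no collar dropout, no fix-rate bias, no terrain barriers,
no prey dynamics, no denning).

**Bundled scenarios.** `null` and `lag1-effect` cover one six-month dry
season, 16 km square world, two individuals per species at 15-min
sampling.  In `lag1-effect` subordinate A's zone-attraction slope is
1.2 (attraction probability rising from ~0.10 at median temperature to
~0.69 two sd warmer); all other slopes are zero.  The slope was chosen
at design time so the programmed effect is comfortably recoverable at
this scale.

## Preprocessing

* Hourly regularisation assigns each top-of-hour the nearest raw fix
  within ±30 min, greedily by |Δt| with ties to the earlier hour; each
  raw fix serves at most one hour.  The operation is idempotent.
* Activity: active iff the displacement to the next hour's fix is
  ≥ 20 m (the collar-error-motivated movement threshold), attributed to
  the interval's start hour.
* Temperature is centred/scaled with the n−1 denominator.  The default
  scope is per season, matching the season-specific models; `z_lag1`
  of day d is defined as `z_lag0` of day d−1 *after* scaling, so the
  lag alignment is exact under any scope.
* The pseudoreplication filter computes, once, the fraction of
  concurrent fixes (2.5 min rule) within 400 m for every within-group
  pair, then repeatedly removes one member (seeded uniform draw) of the
  first pair in id order exceeding 50% overlap.  Pairwise overlaps do
  not change as individuals are removed, so the one-pass computation is
  exact.
* Denning-type exclusions are supplied as per-individual date
  intervals; no detection algorithm is attempted.

## Encounters

Fixes from two animals are concurrent when |Δt| ≤ 150 s; candidate
pairs are matched greedily by smallest |Δt| (ties to the earlier fix of
the first track) with each fix used at most once.  A dyad-day row
exists only for days with at least one concurrent pair (minimum
distance is undefined otherwise; a config switch can instead count such
days as non-encounters).  Encounter = minimum daily distance ≤ 400 m,
with 600/800/1000 m sensitivity settings; dyads whose global minimum
distance exceeds 1000 m (5000/10000 m settings) are excluded as pairs
that never co-occurred.  Encounter sets nest across thresholds by
construction, and the pipeline verifies the nesting on every run.

## Rolling home ranges

The BBMM utilization distribution is the duration-weighted average over
consecutive-fix bridges of the time integral of the bridge's Gaussian
density, with variance `T a(1-a) σ²_m + ((1-a)² + a²) δ²`.  Choices:

* **Motion variance σ²_m** maximizes the leave-one-out likelihood in
  which each odd-indexed fix is Normal(linear interpolation of its
  neighbours, the variance above).  On error-free Brownian tracks this
  model is exact and σ²_m is recovered within a few percent at
  n = 2000.  Note the variance model conditions on the *observed*
  neighbours and does not add the centre fix's own error term, so with
  large δ relative to the motion signal the estimate absorbs part of
  the location error.
* **Location error δ** defaults to 20 m, consistent with the 20 m
  movement threshold.
* **Quadrature.** The bridge integrand has boundary layers of width
  ~δ²/(Tσ²) at a = 0, 1 where the variance collapses to δ².  The α
  integral therefore uses composite Gauss–Legendre panels under the
  substitution a = sin²(πu/2), which clusters nodes at the endpoints;
  128 nodes reproduce adaptive quadrature to < 10⁻⁷ per cell.  Rolling
  windows use 12 nodes (mass is renormalized exactly; only the shape
  loses a little fidelity).
* **Rolling windows.**  The home range for date d uses days d−30…d−1
  and requires ≥ 24 distinct data days.  Each bridge's density is
  evaluated once on a shared grid and binned by its start date; a
  rolling sum over day layers then yields every window in time linear
  in tracking days.  Bridges spanning gaps > 6 h are skipped.
* **Isopleth.**  The home-range region is the highest-density cell set
  holding 95% of UD mass (level configurable; never stated in the
  source analyses).  Grid resolution defaults to 100 m (150 m in the
  bundled pipeline) with a buffer of 3 × the maximum step.
* The pipeline estimates one σ²_m per individual (not per window) and,
  by default, computes subordinate-in-dominant-range proportions only;
  `both_directions: true` adds the reverse.

## Additive models (GAMM engine)

All three binomial responses share one penalized-spline engine:

* **Bases.**  Cubic B-splines, k = 10 for temperature smooths, k = 8
  for day of year (cyclic only for full-year fits), cyclic wrapped
  splines for sun time, and double-centred tensor interactions
  (marginal sum-to-zero constraints applied on both margins, one
  penalty per margin) for sun time × temperature.  Every smooth is
  centred by a sum-to-zero constraint.
* **Penalty.**  Second divided differences on the Greville abscissae,
  so the penalty null space is exactly the linear functions and an
  infinite penalty collapses a smooth to a straight line (index-based
  differences would bend near clamped boundary knots).
* **Fitting.**  Penalized IRLS with a trust region on each update and
  monotone step-halving on the penalized deviance (exact objective when
  ρ = 0).  With ρ = 0 and no random effect the fit agrees with an
  independently coded penalized logistic regression to < 10⁻⁶.
* **Smoothing selection.**  Nelder–Mead minimization of
  `n·deviance / (n − 1.4·edf)²` over log smoothing parameters (the 1.4
  inflation guards against overfitting and keeps null-model rejection
  rates at or below nominal).  Warm-started PIRLS makes each evaluation
  cheap.
* **Random intercept.**  One ridge-penalized indicator column per
  dyad/individual, its precision selected alongside the smoothing
  parameters; population-level predictions set the block to zero.
* **AR(1).**  ρ is the lag-1 autocorrelation of standardized working
  residuals within groups (clipped to ±0.9), applied by whitening the
  working model rows; smoothing parameters are re-selected once under
  the estimated ρ.
* **Overdispersion.**  The proportion-in-range response (counts of
  autocorrelated hourly fixes) is strongly overdispersed relative to
  binomial sampling, so binomial-counts fits estimate a quasi-binomial
  scale φ from the Pearson statistic and inflate the coefficient
  covariance by it.  Without this, a no-effect pair shows spurious
  significance.  Bernoulli responses keep φ = 1.
* **Inference.**  Per-smooth p-values are Wald statistics on the
  smooth's coefficient block against the (φ-scaled) posterior
  covariance, with rank set by the rounded effective degrees of
  freedom — an acknowledged approximation; its calibration is checked
  empirically (≤ 10% rejection at α = 0.05 under a null generative
  model, 50 replicates).
* **Fold changes.**  Predicted response at the 80th (or 90th) vs 50th
  percentile of the training rows' unscaled daily maxima, with day of
  year and the other lag at their medians and random effects at zero;
  CIs by the delta method on the log ratio.

## iSSA

Used steps are hourly displacements ≥ 20 m; a turning angle exists only
when the previous retained step is contiguous.  Gamma (lengths) and von
Mises (angles) are fitted by ML per species × season (κ capped at 500
for degenerate inputs).  Each used step is paired with 150 available
steps drawn from those distributions, applied to the previous bearing
(uniform heading when none exists), with endpoints resampled up to 10
times if outside the raster; strata that cannot reach the full 151
rows are dropped.  The conditional-logistic likelihood is maximized by
Newton iteration (agrees with a brute-force optimum to < 10⁻⁹) with a
tiny ridge (10⁻⁶) for numerical stability; covariates are habitat
one-hots (mopane reference), habitat × z_lag0/z_lag1, step length, log
step length (config flag to drop), cos(turn angle), and a 4-df cubic
m-spline of day of year.  Day of year and any temperature main effect
are constant within a stratum, carry no likelihood information, and
shrink to ~0 under the ridge — which is exactly why temperature enters
only through habitat interactions.  Cluster-robust covariance treats
each individual's strata as one cluster; coverage of the resulting 95%
CIs is checked by simulation (≥ 90% over 20 replicates of 30
individuals × 100 strata).  Relative selection strength is
`exp(β_h + β_h:lag0 z₀ + β_h:lag1 z₁)` with delta-method CIs.

## Activity overlap

Sun time maps [sunrise, sunset] linearly onto [π/2, 3π/2] and the
night onto the complementary arc, so the anchors hold exactly on every
day.  Activity densities are model predictions on a 512-point grid of
circular cell midpoints at the 20th/80th temperature percentiles
(other lag at its median), normalized to integrate to one.  The
coefficient of overlapping Δ = ∫ min(f_a, f_b) uses the midpoint rule,
which on a uniform circular grid has the same weights as the periodic
trapezoid rule and is exact for piecewise-constant densities.  CIs
come from 1000 (500 in the pipeline) multivariate-normal draws of each
model's coefficients; a temperature effect is declared when the 95%
CIs at the two percentiles are disjoint.

## Problem sizes and runtimes

The test suite and acceptance script run on deliberately desk-scale
problems: six-month scenarios with six animals at 15-min sampling
(~10⁵ fixes), n = 2000–5000 for recovery checks, 50 replicates for
GAMM power/calibration, 20 replicates (10 in the acceptance script)
for iSSA coverage, and 250 strata per individual in the pipeline's
iSSA stage.  These sizes were chosen so the full suite completes in a
few minutes while keeping every statistical check well-powered.

## Known limitations

* The GAMM engine is a working-correlation (GEE-style) approximation,
  not a full mixed-model likelihood; ρ and the random-intercept
  variance are nuisance parameters, not inferential targets.
* Smooth p-values are approximate; borderline values near 0.05 should
  not be over-read.
* The BBMM σ²_m estimator inherits the leave-one-out variance model's
  treatment of location error (see above).
* The generator's movement model is a CRW with logistic zone
  attraction; real trajectories violate this in many ways, so passing
  recovery tests validates the estimators under the stated generative
  model only.
* Conditional-logistic separation (a habitat never used) is handled by
  coefficient capping with a warning, not by penalized likelihood.
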