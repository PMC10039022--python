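# Methods

This note documents the models, estimators, numerical choices and
known limitations behind `translocmove`, in the order the pipeline
runs them.

## Trajectory preprocessing

Raw GPS tables are cleaned in a fixed sequence: PDOP filter, cadence
thinning, homing detection, censoring, truncation.

- **PDOP filter.** Fixes with PDOP strictly greater than 9 are
  removed. Fixes with no PDOP recorded are kept — absence of the
  diagnostic is not evidence of a poor fix.
- **Thinning to 2 h.** Collars on mixed schedules (15-min, 1-h, 2-h)
  are reduced to the common 2-h resolution by greedy forward
  selection: keep the first fix, then repeatedly the fix closest to
  (last kept + 2 h) within ±15 min. Fixes are only ever selected,
  never interpolated, so the output is a subset of the input and the
  operation is idempotent. Gaps re-anchor the schedule at the first
  fix after the gap; the ±15-min tolerance is chosen so 15-min and
  1-h schedules thin cleanly. Thinning is not phase-aligned to the
  clock hour.
- **Homing.** For a translocated animal, the first fix within 1.6 km
  (the radius of a disc with the 8.3 km² mean resident home-range
  area) of the capture site during the first 10 days triggers
  reclassification: the animal becomes a resident at its capture
  site and fixes from release up to (but excluding) the return are
  censored. Both radius and window are configurable
  (`PreprocessConfig.homing_radius_m`, `homing_window_days`; a window
  of 0 disables the rule). The animal's release-habitat label is not
  changed by reclassification.
- **Days.** Day 1 starts at the first retained fix's local midnight;
  the timezone offset is configurable (`tz_offset_hours`, default
  UTC, which is what the synthetic data use). Tracks are truncated
  90 days after the (possibly re-based) start.

## Dynamic Brownian bridge movement model

Between fixes a and b separated by T seconds, the position at
fraction α is isotropic bivariate normal with mean a + α(b − a) and
per-coordinate variance Tα(1−α)σ²ₘ + (1−α)²δ² + α²δ², with
telemetry-error SD δ = 15 m on both endpoints.

- **σ²ₘ estimation.** The classical leave-one-out estimator: odd-
  indexed interior fixes are scored against the bridge between their
  temporal neighbours, and σ²ₘ maximizes the product of those
  bivariate densities. The 1-D search runs on log σ²ₘ (bounded,
  `scipy.optimize.minimize_scalar`) and is compared against the
  σ²ₘ = 0 boundary; a track whose apparent movement is within
  telemetry error collapses to 0. A perfectly constant-velocity
  transit is exactly linear interpolation, so it also yields σ²ₘ ≈ 0
  — the parameter measures deviation from the straight bridge, not
  speed.
- **Sliding-window break test.** Windows of 11 fixes slide along the
  track; within each window the single-σ²ₘ fit is compared by BIC
  with fits allowing one variance break at candidate positions at
  least 5 fixes (the margin) from both edges — for the 11/5 default
  the single admissible break is the center fix. Both models are
  scored on the identical leave-one-out terms; under a break at fix
  b a scored fix belongs to the left segment iff its index < b. The
  BIC sample size counts two scalar observations per scored fix
  (each leave-one-out residual is bivariate), k = 1 vs 2 variance
  parameters. Each window contributes its break-resolved estimate to
  every step it contains (the margin constrains only breakpoint
  placement); a step's final σ²ₘ is the mean over all containing
  windows. Tracks shorter than one window fall back to a single
  static estimate. The 11-fix windows score only five fixes, so
  per-window estimates carry irreducible sampling noise (relative SD
  ≈ 0.45); profiles on homogeneous tracks typically show a
  coefficient of variation near 0.4.
- **UD rasterization.** Each bridge is discretized at 10 midpoint
  interpolation fractions; each position's Gaussian density is
  evaluated at cell centers (cell mass = center density × cell area
  — a documented approximation bounded by the grid-refinement test),
  weighted by bridge duration, summed and normalized to total mass
  1 ± 1e−6. The grid covers the track's bounding box padded by 3×
  the largest positional SD; a degenerate (single-point) extent
  expands to a minimum 10×10 cells. Default resolution is 30 m
  (matching the landcover grid); it is a sensitivity knob, and the
  moving-window analyses below use 60 m where noted.
- **Isopleths.** The level-p area is the smallest set of cells whose
  cumulative mass reaches p, taking cells in decreasing mass order
  with row-major tie-breaking (deterministic); 1 ha = 10⁴ m².
- **KDE home range.** For release-site assessment, a bivariate
  normal kernel with the reference bandwidth h = σ̂ n^(−1/6),
  σ̂ = √((var_x + var_y)/2), measured with the same isopleth rule.
  Release-site composition buffers the release point with a disc of
  the mean resident home-range area (8.3 km² → r ≈ 1.63 km) and
  counts raster cell centers by class.

## Moving-window metrics and phase detection

Each day's window is the day itself plus three days on each side,
truncated at the series edges (day 4 spans days 1–7; day 1 spans
days 1–4). The dynamic variance profile is estimated **once per
animal on the full track**; each day's UD then integrates only the
bridges inside that day's window, reusing the global per-step
variances (a per-window refit is available as an option). Days whose
window holds fewer than 11 fixes yield missing values. Daily
distance sums step lengths by the day of each step's terminal fix,
so the series total equals the path length exactly; NSD is the
squared displacement of the day's last fix from the release site.
Group series average across animals per day (SE = sd/√n, reported
only for n ≥ 2; days with fewer than the nominal 12 fixes still
contribute).

A translocated group's transition is the first day its mean 95%
range area is at or below the resident reference — by default the
grand mean of the matching resident group's daily means over the
horizon (a day-matched comparison is available behind
`WindowConfig.resident_reference`). The crossing day is the *last*
exploration day: a group crossing on day 29 has exploratory days
1–29. Because windows overlapping the switch still contain
exploratory track, the detected crossing structurally lags the true
behavioral switch by roughly the window half-width (+2 to +4 days in
recovery experiments with T* = 25).

## Step-selection functions

- **Kernels.** Five empirical movement-kernel families: residents
  pooled across habitats, and translocated × release habitat ×
  phase. A step's phase is that of its terminal fix's day. Kernels
  applied to animal i never contain i's own steps; step lengths and
  turning angles are stored and resampled independently (standard
  SSF practice; the joint dependence is not preserved).
- **Random steps.** 20 alternatives per used step: sampled (length,
  turn) pairs applied to the previous observed heading from the
  step's origin. First steps (and steps after a zero-displacement
  fix) have no defined heading and are skipped. Sampling is seeded
  per stratum from (seed, animal index, step index), so results are
  independent of iteration order.
- **Habitat annotation.** Endpoint class from the 30-m raster with
  half-open cells (edge points belong to the right/upper cell).
  Endpoints off-raster or in excluded classes (developed,
  cultivated, open water, barren) invalidate the alternative; a
  stratum whose used step is invalid, or with no valid alternative,
  is dropped and logged.
- **Conditional logit.** Newton–Raphson with step halving on the
  exact stratum-softmax likelihood (analytic gradient and observed
  information), converged at a 1e−10 relative gradient norm.
  statsmodels' ConditionalLogit serves as an independent
  cross-check in the test suite. Standard errors: inverse observed
  information, plus animal-clustered sandwich SEs from per-stratum
  score contributions with an n/(n−1) cluster correction — this
  replaces the random-effect term sometimes added to clogit fits,
  which contributes no point-estimate information and whose variance
  scale is not identifiable from a four-model AIC comparison.
  Separation (a habitat used always/never within strata) is detected
  as a coefficient walking past ±15 and reported clamped at the
  bound with a warning. A rank-deficient design raises an error
  naming the collinear columns; model ranking uses the `drop` mode,
  which removes data-dependent aliased terms the way clogit
  implementations do. Stratum-constant covariates (status, release
  habitat, diel) cancel from the conditional likelihood, so the
  candidate "habitat × status" formulas are realized as habitat-dummy
  interactions only. Step length (km) is always retained; the
  reference habitat is upland pine, so reported coefficients are
  selection for bottomland/grassland relative to pine. Columns named
  `cov_*` in a strata table enter every model as extra covariates
  (recovery experiments use this for known generative terms).
- **AIC ranking.** The four candidate models are fit on identical
  strata (an error otherwise), ranked by AIC with a ΔAIC ≤ 2
  equivalence flag; the diel post-hoc takes the top base model and
  interacts every habitat term with the nocturnal indicator. Diel
  classification defaults to solar altitude (> 0 = diurnal) from the
  NOAA low-precision solar-position algorithm at the study latitude
  (33.3° N, −81.7° E); a fixed clock window (06:00–18:00) is
  available for tests. The civil-twilight alternative is not
  implemented.
- **Weekly series.** Per group, one conditional logit on nocturnal
  strata with a week-specific bottomland coefficient (13
  release-relative weeks over 90 days), grassland dummy and step
  length; weeks with no within-stratum bottomland variation are
  reported missing.

## Synthetic cohorts

The simulator is SSF-consistent by construction so that fitted
coefficients are estimable: at each 2-h move the agent draws K = 50
candidate steps from a phase-specific kernel and chooses with
probability ∝ exp(β_habitat − a·d), where d is the candidate's
distance to the range center (km) and a the attraction strength.

- Kernels: Gamma step lengths and wrapped-normal turns. Defaults:
  exploration mean 500 m, turn SD 0.4 rad (fast, directionally
  persistent); exploitation mean 160 m, turn SD 1.2 rad.
  Exploration has no attraction (a = 0); exploitation uses
  a = 3 /km, strong enough that settled agents stay within roughly a
  kilometre of their center — matching resident behavior — rather
  than drifting between patches.
- Phases: residents start settled at their start cell; translocated
  agents explore through day T* (default 25) and settle where they
  stand at the start of day T*+1. A `homecoming_prob` fraction
  (default 0.1, close to the 3-of-14 returner rate the rule was
  built for) instead walks home and settles near the capture site,
  exercising the homing rule. Exploring agents can also *chance*
  into their old range — returns are emergent as well as programmed.
- Landscape: a Gaussian random field thresholded at class-fraction
  quantiles (defaults 26% bottomland / 44% upland pine / 28%
  grassland / 2% excluded, 30-m cells, 900-m patches, 30-km extent);
  low field values become bottomland so it forms valley-like
  corridors. Translocations place capture and release in opposite
  habitats at least 8 km apart.
- Observation model: isotropic Gaussian telemetry noise (SD 15 m)
  and Gamma-distributed PDOP with a few percent above the quality
  cutoff. Everything is seeded through one `SeedSequence` hierarchy;
  outputs are byte-identical under a fixed seed.

What the generator does *not* emulate: social grouping and sounder
joining, collar failure and irregular fix success, habitat-dependent
telemetry error, mortality, and landscape features beyond the
3-class mosaic. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated movement model, not
robustness to those real-data complications.

## Recovery-experiment design

Three properties of the chain, found empirically here and documented
because they shape the experiments:

1. **Empirical-kernel attenuation.** Availability sampled from
   *realized* steps (the field practice) is selection-tilted, which
   attenuates fitted coefficients; the attenuation grows with the
   group's true β, compressing group contrasts. Coefficient-recovery
   and model-selection experiments therefore use matched
   availability — kernels sampled from the true generative
   proposals — so the conditional logit is correctly specified;
   the empirical-kernel route is exercised end to end by the
   weekly-trend experiment and the pipeline itself.
2. **Unmodeled attraction.** The settled-phase attraction term
   correlates with habitat through each animal's center location;
   leaving it out inflates apparent selection for the habitat the
   animal settled in. Experiments that involve settled strata supply
   the known distance-to-center covariate (`cov_dist_center_km`).
3. **Measurement-error attenuation.** 15-m telemetry error on 160-m
   settled steps misplaces endpoints relative to 30-m habitat cells
   and attenuates settled-phase coefficients by roughly 10–20%;
   exploration steps (≈500 m) are essentially unaffected, so the
   coverage experiment targets the exploration-phase coefficient.

Experiment sizes (chosen so the whole suite runs comfortably on one
core): coefficient recovery, 20 cohorts of 4 residents + 4
translocated over 40 days; model-selection recovery, 20 cohorts of
8 animals over 30 days on a 400-m-patch landscape (step-scale
selection carries no information when settled movement stays inside
900-m patches, so the finer mosaic is what makes the contrast
estimable); switch-day recovery, 10 cohorts of 6 animals over 45
days at 60-m UD cells; weekly trend, cohorts of 3 over the full 90
days. The demo pipeline defaults to 8 animals, 90 days, 60-m cells.

## Known limitations

- Isotropic telemetry error and isotropic bridges only; no barriers
  or least-cost bridge geometry.
- Cell-center density approximation (not exact cell integration) in
  the UD; bounded by the refinement test at < 5% per halving.
- Cluster-robust SEs are first-order; with very few animals they
  understate between-cohort variability.
- The weekly conditional logit replaces the temporally
  autocorrelated mixed model sometimes used for such series; week
  coefficients are treated as fixed effects.
- Geographic coordinates must arrive projected in meters; no CRS
  handling or reprojection is built in.
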