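# Methods

## The estimation problem

`scrtrend` estimates population density and multi-year trend for a
low-density, wide-ranging animal population sampled by a fixed array of
passive hair-snag detectors ("rubs"). Individuals are identified
genetically from hair, so each field season yields binary detections of
known individuals at known detectors during known collection intervals.
Because detection is imperfect and spatially structured, raw counts
understate abundance; spatial capture-recapture (SCR) corrects for both
by modeling where each animal lives and how detection decays with
distance.

## Model

Each individual `i` has a latent activity center `s_i`, a point
summarizing its space use over the season. Detection of an individual
centered at `s` at detector `x` during one occasion is Bernoulli with
half-normal probability

    p(x, s) = p0 * exp(-||x - s||^2 / (2 sigma^2))

where `p0` is the baseline detection probability at zero distance and
`sigma` (km) is the spatial scale of movement. The baseline is
logit-linear in detector-occasion covariates: season (year factor),
interval duration, Julian midpoint of the interval and its square, a
site-level behavioral response (1 from the occasion after the
detector's first detection of the season, by any individual), canopy
cover and its square, terrain-curvature SD, and a land-ownership
security score. Continuous covariates are standardized with
means/SDs pooled over usable detector-occasions; the constants are
stored with the fit.

Activity centers follow an inhomogeneous-in-time, homogeneous-in-space
Poisson process: density `D_t` (animals per 1,000 km²) is log-linear in
the centered year (`log D_t = b0 + b1 * (t - midspan)`) or fully
year-specific. `sigma` is log-linear (constant or year-specific).
Years ("sessions") are modeled as independent closed seasons and the
sexes are fitted separately, since male and female movement scales
differ severalfold.

The latent centers are integrated over a discrete state space: a 4-km
lattice covering the union of discs of radius `buffer` around the
detectors (disc union, not a bounding box, so the space follows the
array's shape). The buffer should be at least 3 `sigma`; at that
distance the kernel has fallen to `exp(-4.5) ≈ 0.011` of baseline.
`buffer_check` reports the margin after fitting. The lattice is
anchored at the detector centroid snapped to the grid, making
construction deterministic. Seasons with different detector footprints
are masks over one pooled lattice, so pixels align across years — a
requirement for per-pixel growth maps.

### Likelihood

The fit maximizes the full Poisson point-process likelihood with
abundance integrated out analytically. With per-pixel intensity
`mu_t(u) = D_t * A / 1000` (`A` = pixel area, km²),

    logL_t = sum_i log( sum_u mu_t(u) Pr(y_i | u) ) - sum_u mu_t(u) pdot_t(u)

up to the additive constant `-log n_t!`, which is dropped (it does not
involve parameters, so estimates, Hessian standard errors, and AICc
differences are unchanged). `Pr(y_i | u)` is the Bernoulli product
over usable detector-occasions; `pdot_t(u)` is the probability of at
least one detection anywhere. The behavioral covariate is site-level
and computed once from the observed data, so it applies identically to
detected and undetected individuals inside `pdot` and the marginal
likelihood needs no latent capture histories. A consequence worth
stating: dropping the behavioral column is exactly equivalent to
pinning its coefficient at zero (tested).

The density parameter is taken per 1,000 km² so that `mu` per 16-km²
pixel is O(0.1–1): the likelihood is invariant to this scaling (halving
`D` while doubling `A` changes nothing — tested), it only conditions
the optimization.

### Derived quantities

* **Density**: `D_t` back-transformed from the log scale with lognormal
  Wald intervals (asymmetric, strictly positive).
* **Trend**: the per-interval finite rate of change
  `lambda = (D_end / D_start)^(1/m)` over `m` annual intervals. For a
  linear log-density model this is `exp(b1 * span / m)` with exact
  delta-method SE `lambda * se(b1) * span / m`; for year-specific
  density the delta gradient of `log lambda` is contracted against the
  full parameter covariance, including the covariance between the two
  density parameters. CIs are 95% Wald on the natural scale.
* **Realized density surface**: per-pixel posterior-mean number of
  activity centers, `Dhat_t(u) = sum_i Pr(s_i = u | y_i, theta-hat) +
  mu_t(u) (1 - pdot_t(u))`. The detected mass sums exactly to the
  number of detected individuals and each individual's posterior sums
  to 1 (tested to 1e-8/1e-10).
* **Local growth**: per-pixel `lambda(u) = (Dhat_end(u)/Dhat_start(u))^(1/m)`,
  restricted to pixels sampled in both seasons; unsampled or zero-start
  pixels are explicit missing values, never silent zeros, because
  growth outside the sampled area is not identified.
* **Regional growth**: realized density summed within each labeled
  region, then the geometric-mean rate. No SE is attached at pixel or
  region scale — the fitted covariance refers to the whole state space
  and cannot be partitioned.
* **Pooled growth**: sex-specific densities are summed within season
  before the rate is taken (the pooled rate always lies between the
  sex-specific rates).

### Effort and outliers

Sampling effort per season is the sum over detectors of collection
interval lengths in days (days accrue only after the hair-clearing
visit; a detector with a clearing visit only contributes zero — the
schedule defines no sampled interval).

Rare long-range movements can dominate the fitted movement scale. For
each individual-season the maximum pairwise distance among detection
locations is computed; spans above a configurable threshold (default
100 km, far above routine movements but below translocation-scale
displacements) are flagged together with the single detection whose
removal most reduces the span (ties broken by table order).
`outlier_sensitivity` refits the model set with and without the flagged
detections and reports densities, movement scales and trend side by
side; the recommended reading is the paired comparison, not either arm
alone.

## Fitting: numerical choices

* Optimizer: BFGS on the unconstrained link scale, 3-point
  finite-difference gradients, gradient tolerance 1e-5, at most 500
  iterations. (2-point gradients stall with precision loss before the
  tolerance on log-likelihoods of magnitude ~1e3.)
* Starting values: `log D` from the naive closed-population count
  (detected individuals per unit area — a deliberate underestimate),
  `logit p0 = -2`, `log sigma` from half the mean maximum distance
  moved among recaptured individuals, falling back to twice the pixel
  spacing when there are no spatial recaptures.
* Covariance: inverse of a central finite-difference Hessian with
  relative step 1e-4 per coordinate. A fit whose Hessian is not
  positive definite is flagged non-converged (its pseudo-inverse is
  kept for diagnostics only); interval-producing functions refuse
  non-converged fits.
* Non-finite likelihood values (overflow at extreme parameters) return
  +inf with a logged warning so the line search can recover.
* All pixel sums are computed in log space via log-sum-exp; survival
  probabilities via `log1p(-p)` with `p` capped just below 1.
* AICc uses `n` = number of distinct individuals detected, pooled over
  the seasons in the fit — individuals are the independent units of
  the marginal likelihood. `n - K - 1 <= 0` yields AICc = +inf rather
  than a negative penalty.

## The synthetic-data generator

Real datasets of this kind are access-restricted, so the generator
produces datasets with the statistical structure the model assumes plus
the field features that stress it:

* a jittered-grid detector array with uneven per-detector visit
  schedules (one clearing visit, then 1–4 collection visits at 25–50
  day intervals, redrawn per season);
* spatially smooth site covariates (Gaussian-kernel random fields,
  ~10–12 km correlation length): beta-shaped canopy percentage,
  lognormal curvature SD, and a 4-level ordinal security score;
* a spatial Poisson population with a northward log-density gradient
  (default 0.04 per km, concentrating animals severalfold toward the
  north) and multiplicative annual growth;
* half-normal space use with sex-specific scales and optional
  logit-scale covariate effects on the baseline, including a
  site-level behavioral reinforcement updated sequentially within the
  season;
* an injection operation that adds one detection at an existing
  detector approximately a requested displacement from an individual's
  detection centroid (errors if no detector lies within 25% of the
  displacement).

Default ("desk") scenario: 49 detectors on a 30-km square, 4-km
lattice, five seasons spanning eight annual intervals (2004, 2009–2012
— one early season, a gap, then four consecutive seasons, as in
multi-year rub surveys; the wide span is what identifies the trend),
female density 30 per 1,000 km² at the mid-span year growing 5% per
year with `sigma` = 4 km, males 22 per 1,000 km² with `sigma` = 8 km,
`p0` = 0.1. Per-sex state spaces use 3-`sigma` buffers (12 km females,
24 km males), giving ~2,400 km² (females) — roughly a twentieth of the
motivating ecosystem scale so the full pipeline runs in minutes. A
`paper_scale_scenario()` at study scale exists but is not exercised by
the tests. The outlier scenario adds a 4-detector satellite cluster
~190 km south of the grid and uses three evenly spaced seasons (2004,
2008, 2012) so the paired refits stay fast.

What the generator does *not* emulate: genotyping error or partial
identity, movement paths within a season (only centers plus a kernel),
open-population dynamics (each season's population is drawn
independently, so realized growth is exact only in expectation),
between-year fidelity of activity centers, and individual
heterogeneity in `p0` beyond the modeled covariates. Passing
recovery tests therefore show that the estimator inverts its own
generative assumptions at realistic sample sizes — not that those
assumptions hold in any particular field system.

Parameter-recovery experiments (50 replicates in the test suite, 20 in
the acceptance script) use a homogeneous density (gradient 0) so the
fitted family is well specified; the gradient default stays on for the
pipeline demonstrations, where it produces the known mild bias of
fitting a homogeneous-density model to a spatially concentrated
population — visible as underestimated density but a nearly unbiased
trend, since the gradient is constant over time.

## Known limitations

* Density is homogeneous within season; spatially varying density
  covariates are out of scope (the density *surface* heterogeneity is
  recovered a posteriori via the realized surface instead).
* Closed-population within and between seasons; no survival or
  recruitment parameters.
* The behavioral response is site-level; individual-level trap
  happiness/shyness and other unmodeled individual heterogeneity bias
  density but largely cancel in trend if stable across years.
* A finite-mixture translocation effect (separate `p0`/`sigma` for
  translocated animals) is noted as an extension and not implemented.
* Wald intervals rely on asymptotic normality on the link scale; with
  few detected individuals they can be optimistic.
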