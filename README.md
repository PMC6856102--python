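# scrtrend

Spatial capture-recapture (SCR) estimation of population density and
multi-year growth rates from detector-array encounter data — the kind
of dataset produced by collecting hair at natural bear rubs and
identifying individuals genetically. It is aimed at quantitative
ecologists who need ecosystem-wide *and* spatially explicit trend
estimates for low-density, wide-ranging species sampled with passive
detectors.

## What it computes

Each individual has a latent activity center `s`; detection at a
detector `x` during one collection interval is Bernoulli with
half-normal probability

    p(x, s) = p0 · exp(−‖x − s‖² / 2σ²)

with the baseline `p0` logit-linear in detector-occasion covariates
(season, interval duration, date, a site-level behavioral response,
canopy, terrain curvature, land-ownership security). Density `D_t`
(animals / 1,000 km²) is log-linear in year or year-specific; σ is
constant or year-specific; sexes are fitted separately. Maximization
of the full Poisson point-process marginal likelihood over a 4-km
state-space lattice gives MLEs with Hessian standard errors; models
are ranked by AICc weights. From a fit the package derives

* per-season densities with lognormal Wald CIs,
* the finite annual rate of change `λ = (D_end / D_start)^(1/m)` with a
  delta-method SE and 95% Wald CI,
* realized (posterior-mean) density surfaces
  `D̂_t(u) = Σ_i Pr(s_i = u | y_i, θ̂) + E[n₀(u)]`,
* per-pixel growth maps `λ(u) = (D̂_end(u)/D̂_start(u))^(1/m)` and
  regional rates from summed realized density (no SE below the whole
  state space, by construction),
* effort summaries (cumulative rub sampling days) and flagged
  long-range outlier movements with paired with/without refits.

A synthetic-data module generates complete multi-season, two-sex
datasets with the structure above (spatial Poisson population with a
north gradient and annual growth, uneven visit schedules, smooth site
covariates, behavioral reinforcement, injectable outlier movements),
so the whole pipeline is testable without restricted field data.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on the
desk-scale synthetic study (49 detectors, five seasons spanning eight
annual intervals, true annual growth 1.05 for both sexes):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_fit_models.py
python analysis/03_trends_and_surfaces.py
python analysis/04_outlier_sensitivity.py --seed 1
```

`01` writes the dataset and prints the effort table:

```
seasons: [2004, 2009, 2010, 2011, 2012]
individuals detected: 115 F, 202 M (703 detections)
 session  n_detectors  cumulative_rub_days
    2004           49                 5056
    ...
state space (F): 152 pixels, 2432 km²
```

`02` ranks four density/σ structures per sex; with this seed the true
structure (linear log-density, constant σ) wins for both sexes, e.g.
females:

```
                                     model  K    dAICc   weight    cumwt
D~linear p0~int + dur + beh sigma~constant  6 0.000000 0.699805 0.699805
  D~year p0~int + dur + beh sigma~constant  9 2.825409 0.170391 0.870196
...
sigma (km): {2004: 4.18, ...}        # truth: 4.0
```

`03` turns the top fits into trends and maps:

```
F: lambda 1.035 (95% CI 0.964-1.107) over 8 annual intervals
M: lambda 1.046 (95% CI 0.990-1.101) over 8 annual intervals
pooled (both sexes): lambda 1.040
```

Both sex-specific CIs cover the true 1.05; the pooled rate lies
between the sex-specific rates. `04` injects a single 190-km
detection and refits year-specific models with and without it:

```
season 2008: sigma 129.5 vs 4.5 km; density 18.4 vs 50.4 per 1,000 km²
lambda with outlier:    1.192 (SE 0.109)
lambda without outlier: 1.136 (SE 0.068)
```

— one extreme movement inflates the fitted movement scale by an order
of magnitude and halves the affected season's density, while the
trend moves by well under two pooled SEs. That is exactly why the
package flags such movements and reports both arms.

A `scrtrend` console command exposes the same steps for file-based
workflows (`scrtrend simulate | validate | effort | flag-outliers |
statespace | fit | select | trend | surfaces`; see `--help`).

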