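# stepsift

Integrated step selection analysis (iSSA) and GPS-cluster kill-site
modelling for predator telemetry on logged landscapes — with a fully
synthetic landscape and movement simulator, so every estimation stage can be
verified by parameter recovery without any field data.

## Who this is for

Movement ecologists asking how anthropogenic disturbance — cutblocks of
different ages, linear-feature networks (roads, trails, seismic lines) —
shapes a predator's habitat selection, movement rates and kill-site
distribution. The motivating system is wolves and moose in a heavily
salvage-logged sub-boreal landscape: hourly GPS collars on ~10 wolves in 5
packs, raster habitat covariates, and moose kill-sites found by
ground-truthing spatiotemporal GPS clusters. Raw data of that kind are
rarely shareable, so the package ships a generative counterpart of the
estimator: simulate trajectories from a known selection process, re-estimate,
and check that the truth comes back.

## The model

**Step selection.** Successive relocations form *steps*. Each observed
(used) step is matched with 10 random *available* steps sharing its start
point, drawn from a tentative movement kernel — gamma step lengths
(shape k0, scale θ0), von Mises turn angles (mean 0, concentration κ) —
fitted to the pooled data. A conditional logistic regression over these
matched strata maximises

    ℓ(β) = Σ_s [ βᵀx_used(s) − log Σ_{j∈s} exp(βᵀx_j) ]

where x holds habitat covariates (land-cover dummies, cutblock age class
and size, ln distances to water / linear features / forest edge, NDVI,
linear-feature density), ln(SL), and the interactions of Table-style
candidate models: every model carries `ln(SL)` and `ln(SL):sin(hour)` with
`sin(hour) = sin(4π(hour−6)/24)` (activity peaks at dawn and dusk). Seven
candidate models (Prey, LF network, Cutblock, and their combinations up to
Global) are compared per animal per season by AIC; population-level
coefficients come from a 2000-repetition bootstrap that resamples animals
with equal probability, summarised by the median and 2.5th/97.5th
quantiles.

Fitted ln(SL) coefficients update the gamma shape,
`k(x, hour) = k0 + β_lnSL + Σ_z β_{lnSL:z} z`, giving expected displacement
rates `k·θ0` (km/h at hourly fixes); habitat coefficients give the relative
selection strength `RSS = exp(βᵀ(x1 − x2))`.

**Kill sites.** An iterative-centroid scan over each animal's fixes detects
spatiotemporal clusters (candidate carcass-handling sites). Kill vs random
sites are modelled by logistic regression on covariates summarised within
an 883 m buffer, after removing covariates with VIF > 4; the candidate
family mirrors the step-selection set without movement terms, ranked by
AIC and validated by 10-fold cross-validation with a binned, area-adjusted
Spearman rank correlation.

## Worked example

```python
import numpy as np
import stepsift as ss

land = ss.generate_landscape(seed=7)        # 30 x 30 km synthetic landscape
fixes = ss.simulate_population(
    land, preset=ss.PopulationPreset(n_animals=4, n_packs=2, n_steps=1000), seed=7
)
strata, kernel = ss.prepare_strata(fixes, land, season="summer", seed=7)
models = [ss.fit_clogit(g, ss.global_spec(), animal_id=a, season="summer")
          for a, g in strata.groupby("animal_id")]
pop = ss.bootstrap_population(models, seed=7)

rss = np.exp(ss.log_rss(pop, {"ln_dist_lf": np.log(51.0)},
                             {"ln_dist_lf": np.log(1001.0)}))
near = ss.displacement_rate(pop, kernel, {"ln_dist_lf": np.log(1.0)}, hour=9)
far = ss.displacement_rate(pop, kernel, {"ln_dist_lf": np.log(1001.0)}, hour=9)
```

Output:

```
tentative kernel: shape=1.357, scale=0.437 km, kappa=0.411
ln_dist_lf   median -0.073  95% CI [-0.090, -0.055]
nc           median +0.290  95% CI [+0.120, +0.526]
ndvi         median +1.254  95% CI [+0.718, +1.791]
ln_sl        median +0.158  95% CI [-0.043, +0.356]
RSS, 50 m vs 1000 m from a linear feature: 1.24
displacement at 09:00: 0.705 km/h on a feature vs 0.611 km/h at 1 km
```

Read: the simulated wolves select habitat near linear features (negative
`ln_dist_lf`; a location 50 m from a feature is ~1.2x as likely to be
chosen as one 1 km away, all else equal), prefer greener cells and new
cutblocks, and move ~15% faster on a linear feature than 1 km from one —
the behavioural signature the estimator is designed to measure, here
recovered from a known generative truth (the default truth preset is the
published summer coefficient vector).

The same pipeline is scriptable from a shell:

```
stepsift simulate --out sim/ --seed 42
stepsift issa --fixes sim/fixes.csv --landscape sim/landscape --season summer --seed 42
stepsift kills detect --fixes sim/fixes.csv --radius-m 300
stepsift recover --stage kills --seed 42 --out recovery.json
```

## Layout

- `stepsift.raster`, `stepsift.landscape` — grid rasters (ESRI ASCII I/O),
  synthetic landscape generation, distance/density/edge derivations
- `stepsift.kernels`, `stepsift.simulate` — movement kernels; trajectory,
  kill-cluster and kill-site simulators (the generative model)
- `stepsift.steps`, `stepsift.clogit`, `stepsift.models`,
  `stepsift.population` — fix filtering, step construction, the
  conditional-logit estimator, candidate model sets, AIC selection,
  bootstrap inference, RSS and displacement rates, step-level CV
- `stepsift.killsite` — cluster detection, buffer covariates, VIF
  screening, kill-site logistic models, binned-Spearman validation
- `stepsift.experiments`, `stepsift.cli` — end-to-end recovery experiments
  and the `stepsift` command line

See `docs/methods.md` for modelling assumptions, defaults and limitations.
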