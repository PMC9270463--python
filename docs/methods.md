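# Methods

## The estimation model

Step selection is estimated in the matched used/available design. For
animal *i*, consecutive hourly fixes define used steps; a step enters the
likelihood only if the preceding step exists at the nominal cadence (the
turn angle needs a previous heading) and if it does not cross the seasonal
boundary (winter = Oct 1–Mar 31, summer = Apr 1–Sep 30; a step belongs to
the season of its start fix). Each used step is matched with `n_available`
(default 10) random steps sharing its start point and time, drawn from the
*tentative kernel*: gamma step lengths and mean-zero von Mises turn angles,
both fitted by maximum likelihood to the pooled used steps of the season
("population-level" pooling; a per-animal option exists). The conditional
logistic likelihood is maximised per animal by damped Newton iterations.

Covariate extraction follows one rule everywhere, in the estimator and in
the simulator: main-effect habitat terms are read from the raster cell at
the step **end**; any covariate entering a `ln(SL)` interaction is read at
the step **start** for that interaction. Distances are log-transformed as
`ln(d + 1 m)`; step lengths are floored at 5 m (half a typical GPS error)
before `ln(SL)`; cut size is a z-score over cutblock cells.

Seven candidate models combine three covariate blocks (prey/natural
habitat; linear-feature network; cutblocks) and all include `ln(SL)` and
`ln(SL):sin(hour)`, where `sin(hour) = sin(4π(hour − 6)/24)` encodes
crepuscular activity. AIC picks the best-supported model per animal per
season; Akaike weights summarise support across animals.

Population-level inference is two-stage: per-animal fits, then a bootstrap
that draws animals with replacement (each animal equally likely; an
animal's multiple models split its weight uniformly), averages coefficient
vectors within each of 2000 repetitions, and reports the median and the
2.5th/97.5th quantiles. No mixed-effects model is fitted — the two-stage
design makes fewer assumptions at these sample sizes, at the price of
percentile intervals that run slightly below nominal coverage with ~10
animals (measured ≈ 0.87 mean coverage across coefficients in the recovery
experiment; recorded, not corrected).

**Kernel updating.** Because available steps are proposed from the
tentative gamma, the fitted `ln(SL)` coefficient measures the difference
between the realised and tentative gamma shapes:
`β̂_lnSL ≈ k_realised − k_tent`. The updated shape at covariates x and hour
h is `k(x, h) = k0 + β_lnSL + β_lnSL:sin(hour)·sin(h) + Σ_z β_{lnSL:z}·z`
(z read at the step start), and the expected displacement is `k·θ0` km/h at
hourly fixes. The scale θ is never updated because no untransformed-SL term
appears in the model space; the turn-angle kernel is likewise never updated
(no cos(TA) terms). When the tentative scale differs slightly from the
generative scale (it does, since the realised step-length distribution is a
shape mixture), the missing raw-SL correction is a small unmodelled term —
visible as nothing beyond replicate noise in the recovery experiments.
Recovery reports map the estimated `ln(SL)` coefficient back to the truth
scale by adding `k_tent − k0` per replicate, which is that same identity.

**Derived quantities.** Log relative selection strength between two
locations is `βᵀ(x1 − x2)` over habitat terms; the contract requires the
movement terms of the two vectors to be equal. Step-level cross-validation
partitions strata (never splitting one), refits per fold, and scores each
held-out stratum by the normalized rank of its used step among the 11
candidates (1 = always preferred, 0.5 = uninformative) — the validation
statistic is a recorded package choice, since "subset by step ID" admits
many scores.

## Kill-site pipeline

The cluster detector is an iterative centroid scan: seed on each unassigned
fix in time order; absorb any later fix within `radius_m` of the running
centroid and within `window_hours` of the last absorbed fix, recomputing
the centroid on absorption; emit clusters with at least `min_fixes`
members. Library defaults are radius 300 m, window 96 h, min_fixes 4 —
configurable, because the original field program's algorithm is not fully
published. The matched recovery experiment raises `min_fixes` to 6, matched
to its planted 24-h dwells (25 fixes), which leaves travelling movement
clusterless while keeping every planted kill trivially detectable.

Kill vs random sites are compared by maximum-likelihood logistic regression
(statsmodels' Newton/IRLS fit behind a thin estimator) on buffer
covariates: class proportions (four forest classes, new and regenerating
cutblocks) and mean NDVI within an 883 m buffer; water, edge and
linear-feature distance covariates at the point itself (a `buffer` averaging
mode exists — point values are the default because buffer averaging smooths
the class proportions into near-collinearity). VIF screening removes terms
with VIF strictly above 4, iteratively, largest first. The candidate family
mirrors the step-selection set without movement terms and without cut-size
terms (a buffer is described by proportions, not per-block sizes); AIC ranks
the fits. Model fit is validated by k = 10-fold cross-validation stratified
by label: held-out kill scores are binned into 10 equal-count bins of the
held-out random-site scores, and the Spearman correlation between bin rank
and area-adjusted kill frequency is averaged over folds (empty bins merge,
logged).

## The synthetic landscape and simulator

`generate_landscape` builds all covariates on one grid (default 30 × 30 km
at 100 m, a realistic magnitude for a multi-pack study area at GPS-collar
resolution): quantile-classified Gaussian random fields for land cover
(default mixture 40% conifer, 20% pine, 15% mixed, 10% deciduous, 15%
non-forest) and water (3%); rectangular cutblocks with lognormal areas
(median 50 ha — salvage blocks are large) and uniform harvest years over 30
years, to a 20% active-cut cover target; a Poisson chord process of linear
features at 0.6 km/km²; NDVI as a smooth field on [0.15, 0.85], reduced by
0.25 in new cutblocks. Cutblock cells are recoded to non-forest, so the
land-cover dummies treat cleared forest as the reference class, and the
forest/open partition for edge distances counts cutblocks as open (the edge
definition is a recorded choice; it is configurable). The density window
radius (1000 m) is likewise a recorded default. An empty source layer
(e.g. no linear features) yields a distance sentinel of half the landscape
diagonal, keeping log transforms finite.

`simulate_trajectory` is the generative inverse of the estimator: at each
step, `n_candidates` (default 200) proposals are drawn from the kernel and
one is chosen with probability ∝ exp(βᵀx), with x built by the same
extraction rules. The finite candidate set is a discrete approximation of
the continuous redistribution kernel; 200 candidates leave no measurable
bias at the effect sizes used (checked by doubling). Boundary policies:
`reject` (default) redraws candidates that leave the landscape and errors
after 1000 rounds; `reflect` mirrors endpoints (for strongly directional
kernels, for which rejection can starve in corners); `wrap` treats the
landscape as a torus. The kill-detection experiments simulate travelling
movement (gamma shape 6, scale 0.15 km, κ = 5 — fast, directional) on the
torus: reflection makes ballistic paths hug walls and revisit themselves,
which manufactures spurious clusters that say nothing about the detector.

Kill events pause a trajectory: the dwell period (default 24 h) is inserted
as extra fixes scattered uniformly within 100 m of the carcass and the
remaining fixes shift later. Kill-site *records* are generated separately:
candidate points uniform over the (buffer-padded) study area, accepted with
probability inverse-logit(β_killᵀx) — keeping kills rare (default intercept
−5.5) so that, against uniform random sites, case-control logistic slopes
are estimated without contamination bias. The default kill truth mirrors a
published-style top model (strong positive cutblock and NDVI effects,
strongly negative conifer/deciduous); its edge-in coefficient is zero
because point-mode edge-in/edge-out are structurally complementary in this
landscape — VIF always screens one of the pair, and a well-specified
post-screening model requires the screened term to carry no effect.

Two truth presets ship: the *realistic* default — the published summer
population-median coefficient vector, all 22 global terms verbatim, so
recovery experiments run at the study's own effect sizes — and a
*strong-effects* preset for model-discrimination experiments, where each
block must cost more likelihood than its parameters buy back when omitted.
One identifiability fact matters when reading recovery results: the four
land-cover dummies sum to the forest indicator, which is nearly the
indicator of a positive edge-in distance, so the dummy-vs-edge split is
weakly identified in any landscape of this design (their standard errors
stay ≈ 0.15 even at 24 000 pooled strata). Land-cover contrasts are
therefore estimated without bias but with wide intervals; the precise
recovery checks concern the well-identified terms.

What the generator does **not** emulate: territoriality and home ranges,
pack cohesion or interaction, den-site attraction (den locations enter only
as filter inputs), GPS fix failure and location error beyond the 5 m floor,
seasonal habitat change, prey depletion, scavenging or cluster revisits.
Passing recovery tests therefore demonstrates the estimator's correctness
under its own assumptions — not robustness to these real-data features.

## Numerical choices

- Newton solver: analytic gradient and Hessian; step-halving line search
  with slack 1e-10·(1+|ℓ|); convergence at per-stratum gradient
  infinity-norm 1e-8 (the summed gradient's floating-point floor scales
  with |ℓ|); max 100 iterations; covariance from the inverse observed
  information, symmetrised.
- Identifiability: columns constant within every stratum, or collinear
  after within-stratum centring, raise a rank error naming the terms;
  non-convergence (e.g. separation) is flagged, never silent.
- von Mises κ by inverting `I1(κ)/I0(κ) = mean cos θ` (Brent), capped at
  500 with a warning for degenerate headings; gamma by `scipy` MLE with the
  location fixed at 0.
- VIF uses least-squares R² with an intercept; perfect collinearity reports
  an infinite VIF; the strict ">" rule carries a 1e-9 guard so a VIF of
  exactly the threshold is retained.
- All stochastic stages accept either an integer seed or a Generator; the
  experiment runners fan a single master seed out through SeedSequence
  spawning, and reports replay bit-for-bit (NaN-free JSON).
- Distance transforms are exact Euclidean (cell-centre to cell-centre);
  rasters are row-major, cell-centre registered, with half-open cell
  intervals.

## Problem sizes in the verification battery

The recovery experiment runs the full roster preset (10 animals in 5
packs, 2160 hourly steps each — a 90-day single-season deployment) for 20
replicates; model discrimination uses 6 animals × 800 steps × 20
replicates; the kernel-update identity uses 5000 strata; kill-site recovery
uses 1250 kills against 3750 random sites. These sizes give Monte-Carlo
error comfortably below the tolerances they are checked against while
keeping a full verification run to a few minutes on one CPU.

## Known limitations

- Percentile bootstrap intervals over ~10 animals undercover mildly
  (≈ 0.87 vs 0.95 nominal in the null and recovery experiments).
- The kill/random generator's inverse-logit acceptance leaves a small
  contamination term in case-control slopes when kills are not rare;
  defaults keep acceptance ~1–5%.
- The cluster detector is order-dependent by design (deterministic given
  input order) and does not merge clusters across animals.
- Reported hour is local clock time via a configurable UTC offset; no
  daylight-saving handling.
- One projected metric CRS is assumed throughout; there is no reprojection.
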