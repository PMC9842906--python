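# Methods

This note documents the models, rules and numerical choices implemented in
`dispersalkit`, the defaults they ship with, and what the synthetic-study
generator does and does not emulate.

## Departure statistic

Departure to natal dispersal is operationalised as a spatio-temporal
geofence rule: the first time an individual stays *continuously* outside a
nest-centred radius (default 2000 m) for longer than a temporal threshold
(default 2 days). Continuity is judged on the fix sequence. A maximal run
of consecutive fixes beyond the radius is one absence; its duration is the
time from the run's first to its last fix; a single fix inside the radius
terminates the run. Because the transmitters record only during daylight
duty cycles (hourly, 03:00–21:00 UTC February–September, 05:00–19:00 UTC
October–January), overnight gaps carry no information; a gap flanked by
outside fixes on both sides counts as outside time, which is the natural
reading of "continuous absence" when no night fixes exist.

Choices worth making explicit:

* **Strict inequality.** "More than 2 days" means duration > threshold, not
  ≥. A run whose observed span is exactly the threshold does not qualify.
* **Anchor.** The departure timestamp is the first fix of the qualifying
  run. This is conservative and reproducible under duty-cycle gaps; the
  midpoint of the boundary-crossing gap is available via
  `DepartureParams(anchor="gap_midpoint")`.
* **Continuous ages.** Departure age is (departure time − hatching time) in
  real-valued days. Integer ages for reporting are obtained by rounding at
  print time, never inside the analysis.
* **Censoring.** A bird whose record ends without a qualifying run is
  censored (`censored_no_departure`), not assigned an age. A record ending
  mid-absence qualifies only if the observed span already exceeds the
  threshold.
* **Threshold validation.** `threshold_sensitivity` recomputes the age at
  thresholds {1, 2, 3, 5, 9} days. Ages are provably non-decreasing in the
  threshold, and once a track is censored at some threshold it is censored
  at every larger one; both properties are tested.
* **Migration stand-in.** Birds that leave on migration without a local
  departure are excluded. When metadata carries no such flag,
  `migration_flag` uses a documented heuristic: the first displacement
  beyond 50 km from the nest with no later return inside 50 km, occurring
  before any nest-radius absence has reached the temporal threshold. The
  50 km radius is a design choice, configurable, and only a stand-in for a
  field-validated migration call.
* **PFDP.** The post-fledging dependence period subtracts a fixed mean
  fledging age (55 d) from the departure age.

## Communal roosts

Roosts are detected per year from night-adjacent positions of tagged birds
between July and September inside the study polygon dilated by 10 km.
Because the duty cycles leave no true night fixes, "night position" defaults
to the last fix of each UTC day plus the first fix of the following day
(`night_rule="day_boundary"`); a 19:00–05:00 UTC clock window is the
alternative. Each position's revisitation score is the number of entry
events of the pooled night trajectories into the 50 m disc around it (an
entry = an outside→inside transition; a trajectory starting inside counts
one entry). Pooling across individuals is deliberate: the score measures
communal use, not individual site fidelity. The top 5% of positions by
score (at least ⌈0.05·n⌉, all ties at the cutoff kept) are clustered by
k-means (k = 10, 25 restarts, fixed seed) in a local metric projection, and
cluster centroids are reported in lon/lat. The roost-distance covariate is
the geodesic distance from the nest to the closest centroid of the nest's
year.

## Covariates

* **Territory density**: the count of conspecific territory centroids
  within 2 km of the nest, excluding the focal pair's own territory (any
  centroid within 100 m; configurable), divided by the fraction *f* of the
  disc's area inside the study polygon. This area-proportional inflation
  is the most direct reading of correcting edge gaps "proportionally"; it
  never decreases the count, and *f* = 0 (nest outside the study area) is
  an error rather than a silent NaN.
* **Hatching date from feather growth**: the eighth-primary length is
  inverted through a strictly increasing age→length curve by bracketed
  root-finding (Brent, error well below 0.01 d), and the age subtracted
  from the measurement date. The population-specific growth curve is not
  publicly printed, so the curve is configuration: a logistic with
  asymptote 380 mm, midpoint 32 d, rate 0.12 d⁻¹ by default, parameters
  chosen to look like a large raptor's primary growth. Real deployments
  should supply their own curve; everything else is curve-agnostic.
* **Hatching rank**: longest wing in the brood = first-hatched, the rest
  "later" (2nd–4th), an only nestling "singleton". Wing ties break by body
  mass (heavier = earlier), then individual id, so ranks are deterministic.
* **Body condition**: residuals from an OLS regression of body mass on
  tarsus length over the population table. The exact mass–size model used
  in the original supplement is not public; mass ~ tarsus is the documented
  default.
* **Assembly and scaling**: the analysis table joins metadata, departures
  and derived covariates on individual id; unmatched keys are listed and
  rejected, never dropped silently. All continuous covariates are centred
  and scaled within the analysis set; the means and SDs are retained so
  slopes can be reported in natural units (e.g. days per 100 m of
  elevation = scaled slope / SD(elevation) × 100). A screen reports any
  predictor pair with |r| > 0.7.

## Models

The departure-age model is a linear mixed model fitted by REML with a brood
random intercept: fixed effects for feeding treatment, hatching date, rank,
elevation, sex, roost distance, year and territory density, with candidate
two-way interactions pruned stepwise — refit, drop the least significant
interaction with Wald p ≥ α (normal reference, α = 0.05 by default), stop
when all remaining interactions are significant. Main effects are never
dropped. The Wald criterion is a design choice (the original criterion is
unstated); α is configurable and the pruning trace is kept on the fit.

Uncertainty is summarised by simulated-posterior credible intervals: 2000
draws from N(β̂, V̂) where V̂ is the fixed-effect covariance at the REML
fit, intervals from the 2.5/97.5 percentiles. The random-effect variance is
held at its estimate when drawing — the classical two-step "simulate the
posterior" approximation, not a hierarchical Bayes fit. Draws are
deterministic under the seed; a non-positive-semi-definite covariance is an
error with a repair suggestion rather than a silent fix.

The brood random effect is tested by a likelihood-ratio test of the
ML-refitted mixed model against the OLS model. Because the null variance
sits on the boundary of its parameter space the χ² reference is invalid, so
the p-value comes from a parametric bootstrap under the fitted OLS model
(default 500 null simulations).

Mediator models follow the same machinery: hatching date ~ elevation +
density + year with the brood intercept (REML); territory density and roost
distance as OLS models. Reference levels are 2016 for year, female for sex
and first-hatched for rank, so coefficients read as "year [2017]", "sex
[male]" contrasts.

The path analysis is the product-of-coefficients decomposition: per joint
posterior draw, indirect = a·b with a the elevation→hatching-date slope and
b the hatching-date→departure slope, direct = the departure model's
elevation coefficient; intervals are draw percentiles, and the chain is
also reported in natural units (days of hatching per 100 m × departure days
per hatching day = departure days per 100 m). Draws for the two fits are
independent; the two models share no parameters, so the joint posterior
factorises under the normal approximation.

`predict_effects` evaluates scenario grids through the fitted design matrix
with draw-based bands, so figure-style predictions ("males, 2nd–4th
hatched, 2017, other predictors at their mean") are one call.

## Synthetic-study generator

The generator is the package's test bed and defines the conditions under
which all recovery properties are demonstrated. Defaults follow the study
design the package was built around: 105 broods, brood-size distribution
with mean ≈ 1.5 tagged nestlings (so ≈ 158 juveniles), elevations uniform
on 524–1129 m a.s.l., treatment stratified within every 100 m band at the
observed fed fraction (33/105), two seasons (2016/2017), and pre-departure
transmitter failure and migration at 64/239 and 17/239.

Hatching dates follow
`doy = 132.71 + 3.03·(elev − elev̄)/100 m − 0.69·z(density) − 5.99·[2017] +
brood + resid`, with brood SD 2.294 d (the square root of the reported
brood variance 5.26) and a within-brood residual SD of 1.5 d — siblings
hatch within a couple of days of each other, which the published tables do
not pin down. Departure ages come from the full fitted coefficient
structure on scaled covariates (feeding −3.52, hatching date −2.14, rank
+1.49/+0.24, elevation +0.39, sex [M] +3.26, roost distance −2.90, year
[2017] +4.57, density −4.99, year×density +4.44, sex×density +3.38 around
an intercept of 79.47), brood SD 1.789 (√3.20) and residual SD 8.0 d — the
residual SD is not published; 8 d reproduces the reported overall
departure-age SD of ≈ 10 d once covariate and brood variance are added.
Departures are constrained to fall strictly after fledging (rare offending
residuals are redrawn).

Trajectories are duty-cycled hourly daylight fixes. Before the true
departure the bird sits in a bounded nest-centred cloud (SD 400 m, capped
at 1.8 km) with Poisson excursions beyond the fence lasting under a day;
at departure it switches to a biased walk away from the nest (5–10 km/day,
capped at 40 km) with rare configurable day-returns. Departed birds roost
communally every third night, rotating through the year's ten roosts in a
per-bird random order; communal roosts are ~90 m-SD point clouds ("groves")
at mutually separated sites. This usage pattern is a deliberate design
choice: revisitation scoring followed by a global top-5% cutoff recovers
all planted roosts only when every roost is genuinely communal (balanced
use) and spatially extended relative to the 50 m revisit disc — point-like
or luck-of-the-draw usage puts whole roosts below the cutoff, which is a
degenerate regime rather than the structure the method assumes. Migrants
never depart locally; they leave directly at ≈ 100 km/day with no return.
Failed transmitters truncate before the departure. Tracking runs to the
end of September, when autumn migration approaches.

What the generator does **not** emulate: terrain (elevation is a covariate,
not a surface), parent birds, GPS error, battery/solar dynamics beyond the
duty windows, behavioural home-range structure beyond the bounded cloud,
roost occupancy dynamics, or real migration phenology. Passing tests
therefore demonstrate that the pipeline recovers what its own assumptions
encode — detector thresholds, revisitation structure, linear model
coefficients — not that those assumptions hold in any particular field
system.

## Geometry

Coordinates are WGS84 lon/lat on disk; all metric computation uses either
the haversine great-circle distance or a spherical azimuthal-equidistant
projection centred on the study area (IUGG mean radius 6 371 008.8 m).
Distances from the projection origin are exact; pairwise distances are
within ~0.5% of geodesic at study scale, and points beyond 300 km from the
origin are rejected. The spherical-vs-ellipsoidal discrepancy (< 0.5%) is
far below every threshold the analysis uses (50 m, 2 km, 10 km).

## Problem sizes in the test suite

The bundled checks run at sizes chosen to finish comfortably on one CPU:
the detector-versus-oracle comparison uses 500 simulated tracks of ≤ 500
fixes (2 h fix interval); roost plant-and-recover uses one full default
study; coefficient recovery and credible-interval calibration use 200
replicate studies of 158 juveniles in 105 broods; the bootstrap LRT in unit
tests uses 100 null simulations (500 is the library default).

## Known limitations

* The brood random intercept is weakly identified at ~1.5 juveniles per
  brood; single-study variance estimates are noisy (fixed-effect recovery
  is unaffected and is what the tests assert).
* The stepwise Wald pruning inherits the usual caveats of stepwise
  selection; it is faithful to the analysis it reimplements, not a
  recommendation.
* `revisit_counts` is O(focal × fixes) per individual; fine at study scale
  (~10⁴ night positions), not designed for millions of fixes.
* The migration heuristic and the night-position proxy are documented
  stand-ins for field definitions that are not public.
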