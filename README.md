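# dispersalkit

Tools for analysing the **onset of natal dispersal** in GPS-tagged juvenile
raptors. The package was built around a red kite (*Milvus milvus*) field
design on an Alpine elevational gradient — solar GPS tags on nestlings,
hourly daylight duty cycles, a food-supplementation experiment stratified by
elevation — and implements the full chain from raw Movebank-style fixes to
the mixed-model and path-analysis inference:

1. **Departure detection** (`dispersalkit.departure`): a juvenile has
   *departed* at the first time it stays continuously outside a 2 km radius
   around its natal nest for more than 2 days. The temporal threshold is
   validated at 1/2/3/5/9 days; the post-fledging dependence period (PFDP)
   is the departure age minus a fledging age of 55 days. Birds that died,
   lost their transmitter, or began migration before departing are excluded
   from the analysis set.
2. **Communal-roost identification** (`dispersalkit.roosts`): night-adjacent
   positions from July–September inside the 10 km-buffered study area are
   scored by revisitation (entry events into a 50 m disc), the top 5% most
   revisited positions are k-means clustered into 10 roosts per year, and
   each nest's distance to the closest roost becomes a control covariate.
3. **Covariates** (`dispersalkit.covariates`): edge-corrected conspecific
   territory density (centroids within 2 km, inflated by the disc fraction
   inside the study polygon), hatching dates inverted from eighth-primary
   feather length via a growth curve, hatching ranks from within-brood wing
   ordering, mass–tarsus body-condition residuals, and the centred/scaled
   analysis table.
4. **Inference** (`dispersalkit.inference`): the departure-age linear mixed
   model (REML, brood random intercept) with stepwise pruning of two-way
   interactions, 95% credible intervals from a 2000-draw simulated
   posterior, a parametric-bootstrap likelihood-ratio test of the brood
   effect, mediator models for hatching date / territory density / roost
   distance, and a product-of-coefficients path analysis splitting the
   elevation effect on departure age into its direct path and its indirect
   path through hatching date.
5. **Synthetic studies** (`dispersalkit.simulate`): a first-class generator
   that draws whole studies — broods stratified by 100 m elevation band,
   hatching dates with an elevational delay, departure ages from the full
   fitted coefficient structure, duty-cycled trajectories with excursions,
   communal roosts, transmitter failures and pre-departure migrants — so
   every stage is testable without any tracking download.

In the scaled-covariate notation used throughout, the core model is

    departure_age_ij = β0 + β_fed·fed + β_hatch·z(hatch) + β_rank + β_elev·z(elev)
                     + β_sex·male + β_roost·z(roost dist) + β_year·y2017
                     + β_dens·z(density) + β_year:dens + β_sex:dens
                     + b_brood(j) + ε_ij,   b ~ N(0, σ²_brood), ε ~ N(0, σ²)

with the indirect elevation effect quantified as the product
a·b of the elevation→hatching-date and hatching-date→departure slopes.

## Worked example

```bash
dispersalkit pipeline demo --out demo_out --seed 0
```

simulates a default-size study (105 broods over two seasons), writes the
tracks and metadata as CSV, re-ingests them, and runs the full analysis in
about 90 s. It prints the filter accounting:

```json
{
  "tagged": 160,
  "excluded_failed": 46,
  "excluded_migrated": 16,
  "censored_no_departure": 0,
  "included": 98
}
```

i.e. of 160 tagged juveniles, 46 failed before departure, 16 left on
migration without dispersing, and 98 entered the models. `demo_out/fits.json`
then holds the coefficient tables: this single run estimated a
feeding-treatment effect of −6.29 d on departure age (fed juveniles depart
younger; the generative truth is −3.52 d, and a single study of this size
carries a standard error near 2 d) and an elevational hatching-date slope of
2.70 d per 100 m (truth 3.03), with 95% credible intervals from the
simulated posterior and the direct/indirect elevation decomposition under
`path`. `demo_out/manifest.json` records seeds, row counts and file hashes;
rerunning the same config reproduces the hashes bit for bit.

The same stages are available as `dispersalkit simulate / depart / roosts /
fit` for use on real Movebank-style exports, and as plain library functions.

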