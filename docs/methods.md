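# Methods

`roostkit` re-implements, as a tested pipeline, a longitudinal analysis of
winter communal roosting in GPS-tracked red kites (*Milvus milvus*): the
detection of communal-roost attendance from nightly fixes, weighted
binomial mixed models of attendance by age, sex and breeding status, the
separation of within-individual behavioural plasticity from selective
mortality, and node-permutation tests of assortative roosting with mates
and kin.  Every stage is exercised end-to-end on a synthetic tracked
population with known generative parameters, so the statistical machinery
can be validated against its own truth.

## Communal-roost detection

Tags record fixes on a duty cycle (07:00–21:00 CET, hourly by default).
Night `d` collects the fixes between civil dusk of `d` (sun 6° below the
horizon, computed from a low-precision solar ephemeris accurate to about
a minute) and the duty end, plus the fixes of day `d+1` before civil
dawn.  Fixes are projected to planar metres with a local transverse
Mercator (ellipsoidal series on WGS84; sub-millimetre round-trip error
over the study extent) and each bird-night is reduced to the
component-wise median of its fixes.

The November–January season is cut into consecutive, non-overlapping
five-night blocks anchored at Nov 1: 18 full blocks plus one two-night
block, 19 per winter, 114 over six winters regardless of the data.  A
bird attends a communal roost in a block when at least two *other* tagged
birds have a nightly median within 300 m (closed ball) of one of its
nightly medians in that block.  By default the proximity may occur on any
pair of nights in the block (`cross_night`), which reduces false
negatives given that only a sample of the population is tagged;
`same_night` matching is available as a switch.  Roost sites are
single-linkage components of the nightly medians under the same radius.

Each bird-block unit receives an observation weight: the mean distance of
its nightly medians outside the study-area polygon, scaled by the global
maximum of that quantity and subtracted from one, so units inside the
area weigh 1 and the farthest unit weighs 0.  Weights down-weight
attendance records from regions where few conspecifics are tagged and a
"non-attendance" is likely a false negative.

Sensitivity of the attendance rate to the radius, block length and
neighbour threshold is available as a grid sweep; attendance is
non-decreasing in the radius and block length and non-increasing in the
neighbour threshold, which the tests verify together with exact
equivalence to a brute-force O(n²) classifier.

## Attendance models

The modelling unit is the bird-block attendance flag (0/1).  Cohorts are
fitted separately: birds tagged as juveniles (known age) get fixed
effects for standardised age, age², sex and breeding status (breeding in
the summer preceding the winter); birds tagged as adults (age unknown,
all breeding) get sex only.  Both include a bird random intercept, a
bird-by-winter random intercept and slope over the standardised
within-winter block index (1..19, standardised with the fixed calendar
constants mean 10, SD 5.477) with estimated correlation — absorbing the
temporal autocorrelation of a bird's season — and a winter random
intercept.  Unit weights multiply the log-likelihood contributions.

### Estimation engine

No installed Python library fits a weighted Bernoulli mixed model with
crossed, correlated random effects, so the engine is implemented here:

* the joint penalised likelihood over (fixed effects, random effects) is
  maximised by penalised IRLS with sparse Cholesky-free `splu` solves;
* variance parameters (log SDs; log-Cholesky for correlated pairs) are
  optimised by Nelder–Mead with explicit initial simplexes and
  fresh-simplex restarts over the Laplace-approximate marginal
  likelihood;
* the fixed effects are then re-optimised against the full Laplace
  objective with the random effects profiled out.  Without this step the
  profiled estimates show the attenuation familiar from `nAGQ=0`
  estimation; with it the estimates agree with glmmTMB to about three
  decimals on matched problems;
* fixed-effect covariance comes from the joint observed information over
  (fixed effects, variance parameters) by central finite differences,
  which propagates variance-parameter uncertainty into the intervals
  (conditional-on-variance Wald intervals undercover);
* a weak gamma(2, rate 0) penalty on the random-effect SDs (penalised ML
  in the style of `blme`) keeps few-level variance terms (e.g. 4
  winters) off the zero boundary, where the intercept interval would
  collapse;
* a ridge of 1e-4 on the fixed effects keeps separated fits finite, and
  coefficients beyond ±15 on the logit scale are flagged as
  quasi-separated.  Constant responses are flagged, never fitted
  silently.

A small fixed-effect bias remains for the few-level winter mean: with
four winter levels any ML-family engine (this one and glmmTMB behave
identically) underestimates the uncertainty the intercept absorbs from
the winter effects, so the intercept's interval covers at roughly 85–95%
rather than 95%.  The covariate effects (age, age², sex, breeding) are
calibrated: simulation from the generative truth at 148 birds × 4
winters covers each in ≥ 18/20 seeded replicates.

### Diagnostics and derived quantities

* *Classification accuracy*: fitted probabilities thresholded at the
  observed event rate; the weighted share of correct classifications.
* *Binned residuals*: equal-count bins of fitted probability with ±2 SE
  bands; a well-specified fit keeps most bins inside the bands, an
  omitted quadratic produces a systematic U-shaped pattern.
* *Adjusted repeatability*: latent-scale intra-class correlation
  R = σ²_bird / (σ²_bird + σ²_winter + π²/3), computed from a fit with
  bird and winter intercepts (the logistic residual variance is π²/3);
  confidence intervals by seeded parametric bootstrap (simulate from the
  fit, refit).  The bird-by-winter term is excluded from the
  repeatability fit, mirroring the convention of rptR-style analyses.
* *Cramér's V* with a χ² p-value quantifies the age–breeding confound.
* *Model comparison*: marginal-likelihood AIC differences (elpd ≈
  log L − k) with standard errors from the pointwise conditional
  log-likelihood spread.  The conditional likelihood itself is not used
  for ranking because flexible random-effect structures flatter it.

## Plasticity versus selective mortality

Restricted to confirmed-dead, juvenile-tagged birds, whose longevity (age
in winters at confirmed death) is known exactly.  Four weighted binomial
models share sex, breeding status, a Julian-date covariate (days from
Nov 1 at the block midpoint, standardised) and a winter intercept, and
differ in: age (quadratic) only; age + bird intercept; longevity + bird
intercept; age + longevity + bird intercept.  An age effect persisting
with longevity in the model indicates within-individual plasticity; an
additional longevity effect indicates selective disappearance.  The
helper labels the outcome `plasticity`, `selective_mortality`, `both` or
`neither` from the 95% intervals of the final model, computes VIFs on the
fixed design (flagging ≥ 2), drops the quadratic age term when fewer
than three age levels are observed (it would be collinear), and skips
the longevity models when longevity does not vary.

## Association analysis

A bird-night is *eligible* when the bird has at least one GPS-tagged
mate (nesting together that season), parent, offspring or intra-year
sibling transmitting in the study region during that five-night block.
Eligible bird-nights are classified by the block's communal flag and by
whether a labelled partner's nightly median lies within the detection
radius that night; dyads with several labels resolve by precedence
mate > parent-offspring > sibling.  Summaries: the four category shares,
the mean distance from the nightly median to the bird's registry nest
(breeding nest when breeding that season, else natal nest) per category,
and the mate / parent-offspring / sibling composition of co-roosting
events.

The null model permutes family identity while leaving all spatial data
untouched: natal-brood assignments are shuffled within each cohort year
(preserving the brood multiset exactly) and breeding-nest slots are
shuffled within each season and sex (two birds are mates in the null only
when assigned the same nest; null pairs therefore stay male-female and
the number of tagged pairs is preserved — sex shapes presence and
attendance, so cross-sex slot mixing would break exchangeability);
sibling,
parent-offspring and mate links, nest coordinates, eligibility and all
statistics are recomputed per iteration through the same vectorised code
path that produces the observed values.  Recomputing eligibility is
essential: holding the observed record set fixed conditions the observed
with-partner rates on partner presence while permuted partners are often
absent, which deflates the null (measured type-I error ~0.5).  With the
full recomputation the one-sided p-values are uniform under the
generator's no-assortment setting (rejection 3–7% at α = 0.05 over 400
runs).  Directional p-values are the proportion of null draws at least
as extreme as the observed value in the direction of the observed
deviation; zero proportions are reported as `< 1/n_iter`.  Fixed-
direction `p_greater`/`p_less` columns support calibration checks.

Within-season trends of mate and kin co-roosting are logistic mixed
models on bird-block aggregates (any co-roosting night in the block)
with the standardised block index as predictor and a bird intercept; a
response without variation (kin co-roosting can be too rare) is skipped
with a warning.

## Synthetic population generator

The generator is first-class, tested code whose defaults describe the
study system: 148 juvenile-tagged and 68 adult-tagged birds over six
Nov 1–Jan 31 winters on a square 387 km² study area (planar metres;
WGS84 export through a declared local transverse Mercator anchored in
western Switzerland); three major roost sites at least 3 km apart plus
five satellites within 0.5–2 km of a major site; hourly fixes on the
07:00–21:00 duty cycle between civil dusk and dawn with 11.3 m per-
coordinate within-night scatter, reproducing a ~18.9 m median pairwise
within-night fix distance.

Attendance truth follows the attendance-model structure with the
juvenile-cohort point estimates as default coefficients (intercept
−0.441, age −0.27, age² −0.453, male +1.731, breeder −1.296 on the
log-odds scale; random-effect SDs 1.624 / 1.852 / 1.394 / 0.345 with
intercept–slope correlation −0.581) plus a linear seasonal logit trend
(−0.15 per standardised block) so November roosts outnumber January
roosts.  The latent attendance state is drawn once per bird × block and
holds for its nights, making the block-level model exactly the
generative model.  Attending birds choose a roost site with
distance-decay weights exp(−d / 5 km) from their anchor (breeding nest,
else natal home range) and sit at the site centre plus 40 m scatter.
Non-attending breeders sit at their nest (30 m jitter); with probability
1 − `pair_coroost_prob` (default co-roost probability 0.7) one pair
member is displaced off-territory for the night.  Non-attending
non-breeders use a home range anchored 1.5 km (SD) from the natal nest;
with probability `kin_coroost_prob` (0.05) they join a tagged relative
for the night.

Demography: breeding can start in the third calendar year with
settlement age ~ N(4.14, 0.90) truncated at 3; pairs form among tagged
breeders (others breed with untagged mates) and share a nest; broods of
1–3 tagged siblings, one quarter of them at a tagged pair's nest (the
parent–offspring links); annual mortality 0.45 / 0.22 / 0.15 / 0.10 by
age with uniform death dates truncating all later fixes; partial
migration (probabilities by sex and age, first-winter females highest at
0.70) realised as a late departure or an early return, so migrants
contribute part of the winter — matching a tracked population where
roughly 53 of 92 winter nights are observed per bird-winter.  A
`cohort_years_before` option lets juvenile cohorts predate the
monitoring window so short windows can carry the age mix (1–7) of the
full study; the parameter-recovery fixture uses 3.  An `assortment=False`
switch makes all positions independent of the registry geometry (random
home anchors, no pair/kin co-location) — the type-I calibration setting
for the permutation test.

What the generator does *not* emulate: flight paths and foraging
movement, weather, untagged conspecifics (roost sizes are tagged-bird
counts), GPS outliers and fix failures, mate switching, and dispersal
out of the study region other than whole/part-winter migration.  Passing
tests therefore validate the statistical machinery under the stated
model, not the field behaviour of real kites.

## Validation harnesses and problem sizes

`roostkit.validation` drives three simulation checks, shared by the test
suite and `scripts/acceptance.py`, with sizes chosen to finish in
minutes on one CPU:

* **Parameter recovery** — 20 replicates of 148 juvenile-tagged birds ×
  4 winters (deep cohorts); each covariate effect must fall in its 95%
  interval in ≥ 18/20 replicates.
* **Plasticity vs. mortality discrimination** — 20 seeds per scenario of
  43 confirmed-dead birds; ≥ 18/20 must be labelled correctly.
* **Permutation calibration** — 400 runs of a 48-bird juvenile-only,
  one-winter, no-assortment fixture with 200-iteration nulls; the
  fixed-direction p-value of the communal-without-partner distance
  statistic must reject at 5% ± 2%.  The juveniles-only design keeps the
  kin shuffle on one large brood stratum; tiny per-sex pair strata would
  tie many null draws with the observed assignment and bias the p-value
  conservative.

## Numerical choices and degenerate inputs

Ties at exactly the detection radius count as inside (closed ball).
Nights with zero qualifying fixes are absent; birds absent from a block
simply contribute no unit.  Units outside the seasonal window are
dropped with a logged count.  An all-inside weight vector is all ones
(no rescaling by a zero maximum).  Empty sensitivity grids, degenerate
polygons, single-level categorical inputs, conflicting pair records and
birds in two broods of one year raise explicit errors.  Timestamps are
stored UTC and interpreted on a fixed CET clock (UTC+1; the season avoids
DST).  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; set iteration never feeds random draws, so
runs are reproducible across processes.

## Known limitations

* The engine is penalised-ML/Laplace, not MCMC: intervals are Wald-type,
  and means of few-level random terms (the intercept under 4 winters)
  undercover slightly; an MCMC backend would widen these honestly.
* Weights enter as log-likelihood multipliers; they are not frequency
  weights, and the effective sample size is reduced accordingly.
* The permutation null treats the tagged sample as the population of
  potential partners; with very few broods or pairs per year the null
  support is small and p-values become granular.
* Nest-distance statistics use the registry nest resolved per bird-year;
  birds without any known nest are excluded from distance summaries
  only.
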