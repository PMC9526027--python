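# Methods

## Model

The package fits hierarchical occupancy/detection models for communities of
`S` species surveyed at `J` sites over `K` repeat visits:

```
Y_ijk ~ Bernoulli(Z_ij * theta_ijk)
Z_ij  ~ Bernoulli(psi_ij)
logit psi_ij    = a_i + sum_t beta_ti * x_tij
logit theta_ijk = c_i + sum_t delta_t * w_tjk
```

Closure is assumed within the visit window (Z constant across a cell's
visits).  At minimum the random-effects structure contains correlated
species random intercepts `(a_i, c_i)`; any occupancy term can carry
species random slopes `beta_ti ~ Normal(mu_t, sigma_t)`.  The discrete `Z`
is marginalized analytically,

```
P(y_ij.) = psi_ij * prod_k theta^y (1-theta)^(1-y)  +  (1-psi_ij) * 1{sum_k y_ijk = 0},
```

which makes the joint density differentiable so Hamiltonian samplers apply;
`Z` is recovered afterwards as its Bayes posterior given the detection
history (`conditional_occupancy`).

### Range covariates

The biogeographic variant adds covariates summarizing each site's position
relative to each species' known range:

* `distance` — signed distance from site to range margin (negative inside),
  transformed by `logit^-1(d / s)`.  The transform asymptotes at 0 in the
  range core, so the species intercepts all describe core-range occupancy —
  the common scale that makes cross-species pooling (exchangeability)
  defensible.  The scale `s` (default 200 km) can be chosen empirically with
  `linearization_diagnostic`, which bins species-site cells by distance and
  picks the candidate scale whose transform best linearizes the logit of the
  naive (>= 1 detection) occupancy proportion.  Naive occupancy ignores
  imperfect detection; that bias is immaterial for transform selection.
  Binning uses 20 equal-width bins over the observed span; empty bins are
  dropped, and bins whose proportion is 0 or 1 get the empirical-logit
  half-count correction rather than being discarded.  Scoring is the
  count-weighted R^2 of the regression of logit-proportion on the
  transformed bin midpoint; ties break toward the smallest scale.
* `std_elev` (and `std_elev2`) — site elevation linearly rescaled per
  species so the species' lower/upper elevational limits map exactly to
  −1/+1; the quadratic term lets occupancy peak inside the range.

Distances are computed with shapely in a projected, distance-preserving
plane with kilometre units.  The package never chooses map projections:
projection is a data decision made upstream, and geographic (lon/lat)
GeoJSON is refused at import.  An optional `ignore_boundary` geometry
removes margin segments (e.g. shorelines) from the nearest-edge search.

### Clipping

Species-site cells where occupancy is a priori negligible are removed
before fitting and become structural zeros outside the likelihood: by
distance to range (boundary cells retained — documented tie-break), by
species-standardized elevation (default ±3), by expert-drawn barrier
polygons (supplied per species, not derived from terrain), and by seasonal
window at the visit level (wrap-around windows supported; a cell is dropped
only when all its visits are).  When several rules remove the same cell the
recorded reason follows the fixed precedence barrier > geographic_distance >
standardized_elevation > temporal.  A detection inside a clipped cell is
treated as a range-map error of omission: `validate_mask_against_detections`
lists such cells and model construction refuses to proceed until the ranges
or mask are fixed, because silently accepting them would let a wrong map
zero out real occurrences.  There is no automatic threshold selection; the
package reports the maximum distance-to-range at which a detection occurred
to inform the user's choice.

### Data augmentation

For comparison, the classical data-augmented formulation is implemented:
`n_pseudospecies` all-zero detection histories are appended, each a
community member with probability Omega (uniform prior), contributing
`log[(1-Omega) + Omega * exp(sum_j all-zero cell loglik)]`.  Species-site
covariates are disallowed in this variant, since pseudospecies have no
range or trait information; site-level covariates with species random
slopes (e.g. raw elevation) remain, which is exactly the degree of freedom
that lets the model explain non-detection by extreme elevational
relationships.  At the desk scales exercised here the fitted variant
resolves the non-detection of pseudospecies mainly by excluding them
(posterior inclusion probability well below one) rather than by ascribing
extreme elevational ranges; `examples/data_augmentation_demo.py` shows and
discusses this behaviour against the range-informed alternative.

## Priors

Defaults (overridable via `Priors` in `ModelSpec`): population means and
fixed coefficients `Normal(0, 2.5)`; hierarchical standard deviations
`Half-Normal(0, 2)`; the intercept correlation uniform on (−1, 1) via a
tanh-transformed parameter; Omega uniform on (0, 1).  The Half-Normal(0, 2)
scale was chosen so that slope heterogeneity of the size the generator
produces (SDs near 1.5 on the logit scale) is not materially shrunk; a
Half-Normal(0, 1) prior measurably biased the slope-SD posterior downward.
Random effects use the non-centered parameterization throughout, with the
intercept pair sharing a Cholesky-correlated bivariate deviation — the
standard remedy for the funnel geometries of small-community hierarchies.

## Inference

`OccupancyModel.fit` runs a self-contained No-U-Turn sampler: multinomial
trajectory sampling, dual-averaging step-size adaptation (default target
acceptance 0.9, configurable), diagonal mass-matrix estimation in
Stan-style expanding warmup windows, tree depth capped at 10 by default,
divergence declared when the Hamiltonian error exceeds 1000.  The gradient
of the marginalized likelihood is analytic; the hot loop is compiled with
numba.  Initialization is the prior mean (zeros on the unconstrained scale)
jittered uniformly by ±0.1.  Default run length mirrors common practice for
these models (4 chains, 1000 warmup + 1000 draws); tests and the acceptance
script use shorter, documented settings.

Convergence is enforced, not just reported: `convergence_report` passes only
if rank-normalized split r-hat < 1.03 for every parameter, there are no
divergent transitions, and the energy fraction of missing information
(E-BFMI) exceeds 0.2 in every chain.  r-hat requires at least two chains;
single-chain fits warn at fit time and the report refuses.

Sampler calibration is tested by reduced simulation-based calibration
(50 replicates of an 8-species model with truth drawn from the priors; rank
statistics checked for uniformity at alpha = 0.01).

## Model comparison

`loo` computes PSIS-LOO: per species-site cell, importance ratios from the
posterior draws are tail-smoothed by a fitted generalized Pareto
distribution (tail size `ceil(min(0.2 S, 3 sqrt(S)))`, arviz
implementation) and the Pareto k-hat recorded; cells with k-hat > 0.7 are
re-evaluated by an exact leave-one-cell-out refit when a hook is supplied
(`make_refit_hook`), otherwise flagged.  The leave-one-out unit is the
species-site detection-history vector, because visits within a cell share
the latent Z and are not conditionally independent.  Moment-matching is not
implemented; exact refit is the unambiguous remedy at the data scales this
package targets.  `elpd_compare` requires identical cell sets (comparisons
with clipped models must be restricted to the retained cells) and reports
overall and per-species differences with standard errors computed treating
cells as independent within species.

## The synthetic-data generator

`simulate_community` draws the kind of data the model assumes: disc-shaped
ranges (centroid + radius) in a flat 1000 × 1000 km plane, so the signed
distance has the closed form `|p − centre| − r` and geometry can be tested
exactly; a uniform 0–3000 m elevational gradient with per-species
elevational limits; correlated intercepts; species random slopes for
elevation and the transformed distance; a time-of-day detection covariate;
and a never-observable pool created by placing centroids at least three
radii beyond the site hull (in 1-D gradient designs, by elevational ranges
entirely above the sampled gradient).  Site elevations are uniform by
default; an optional Beta-shaped elevation distribution emulates sampling
effort thinning toward a gradient's extremes.  The generative links are the
fitted model's, so parameter recovery is well-posed.

Defaults (the reference study conditions; all configurable): 24 species,
96 sites, 4 visits; radii lognormal around 500 km — large relative to the
200 km transform scale, so range cores genuinely reach the transform's zero
asymptote, as they do for continental-scale ranges; intercepts
`(a, c) ~ N((0.5, 0), (0.8, 0.8), rho=0.5)`; elevation slopes `N(0, 0.5)`;
distance slopes `N(−3.5, 1.6)`; time-of-day coefficient −0.3; 10% of
species unreachable.  The distance-slope regime was chosen by a design-time
identifiability analysis: much steeper mean slopes leave most out-of-range
cells all-zero and the slope value censored (any sufficiently negative
slope explains the data equally well), while much flatter slopes remove the
biogeographic signal; no data size repairs censoring.  The continental
surveys this generator emulates have thousands of sites; the scaled-down
defaults preserve the sites-per-species ratio that drives slope
identifiability.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about field data: irregular range shapes and holes, spatial
autocorrelation in occupancy residuals, observer effects and overdispersed
detection, range-map error, multi-season dynamics, and trait-structured
communities.  Model misspecification is exercised only in the deliberate
MSOM-versus-bMSOM contrasts.

## Verification problem sizes

The acceptance-style tests use, as the package's reference scaled design:
20 replicate communities of 12 species × 200 sites × 4 visits for the
recovery, cross-validation and bias batteries (single chains, 200 warmup +
300 draws for the range model); an exhaustive latent-state enumeration
oracle on ≤ 12-cell instances; a 6-cell model with 8000 draws for the
PSIS-versus-exact-LOO check; and 50 SBC replicates at 8 species × 24 sites.
`scripts/acceptance.py` reruns the same computations (12 replicates) from a
single seed.

## Numerical choices and degenerate inputs

* All likelihood terms are computed on the log scale with `log1p`/
  log-sum-exp; the all-masked cell has probability one; a detection with
  psi = 0 returns −inf with a warning.
* Equal distances at a clip threshold are retained; equal linearization
  scores select the smallest scale; constant importance ratios return
  uniform weights with a k-hat sentinel of −inf.
* Elevational limits must satisfy lower < upper; inverted limits, empty
  geometries, geographic CRS, duplicate detection rows, and non-binary
  detections are hard errors with the offending species/rows named.
* Disc ranges are exported to GeoJSON with 256 segments per quarter-circle
  (boundary error ≪ 0.1 km at 500 km radii, three orders of magnitude below
  the transform scale); the generator's truth uses the exact closed form.

## Known limitations

No spatially autocorrelated random fields, no multi-season dynamics, no
abundance (N-mixture) variants, no raster ranges or geodesic distances, no
WAIC or K-fold machinery beyond the exact-refit fallback, no
moment-matching PSIS pass, and no within-chain parallelism.  The
data-augmented variant is provided for methodological comparison, not tuned
for production use; its known fitting pathologies are demonstrated, not
solved.
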