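# bmsom — biogeographic multi-species occupancy models

Multi-species occupancy models (MSOMs) pool information across a community of
species through hierarchical random effects, separating true presence from
imperfect detection using repeat-visit survey data.  Applied at biogeographic
scales — study regions that span many species' range margins — the standard
MSOM has no way to know which species could plausibly occur where, so it
conflates in-range and out-of-range occupancy: in-range occupancy is biased
low, out-of-range occupancy is overestimated, and never-observed species are
either dropped or handled through anonymous data-augmented pseudospecies.

`bmsom` implements the *biogeographic* MSOM: preexisting range information
(range-map polygons, elevational limits, seasonal presence windows) enters
the occupancy regression as species-specific **range covariates** with random
slopes, and severely out-of-range species-site combinations can be removed a
priori (**biogeographic clipping**), becoming structural zeros outside the
likelihood.  It is written for community ecologists fitting occupancy models
to large-scale survey data (breeding-bird atlases, point-count networks on
elevational gradients) who have range maps or range descriptions in hand.

## The model

For species *i*, site *j*, visit *k*:

```
Y_ijk ~ Bernoulli(Z_ij * theta_ijk)        detection given presence
Z_ij  ~ Bernoulli(psi_ij)                  latent occupancy
logit psi_ij   = a_i + x_j' b_i            occupancy regression
logit theta_ijk = c_i + w_jk' d            detection regression
```

with correlated species random intercepts (a_i, c_i) and species random
slopes b_i for the range covariates.  The two range covariates built here:

* **geographic** — the inverse logit of the signed distance from site to
  range margin in units of a scale s (default 200 km):
  `D_ij = logit^-1(d_ij / s)`.  D asymptotes at 0 deep inside the range, is
  0.5 on the margin, and tends to 1 far outside, so the hierarchical
  intercepts describe core-range occupancy on a common scale across species;
* **elevational** — the site elevation linearly rescaled per species so the
  species' lower/upper limits map to −1/+1 exactly, with an optional
  quadratic term.

The latent Z is marginalized analytically, so the joint density is smooth
and fitted with the package's built-in No-U-Turn sampler (adaptive
Hamiltonian Monte Carlo with divergence and energy diagnostics).  Models are
compared by approximate leave-one-out cross-validation with Pareto-smoothed
importance sampling (PSIS-LOO), the leave-out unit being the species-site
detection-history vector.  Richness prediction sums each species' posterior
probability of presence given its detection history — never-observed species
included, because their range information fixes their identities.  A
classical data-augmented MSOM (anonymous pseudospecies with Bernoulli(Ω)
membership) is implemented for comparison.

## Worked example

```python
import bmsom as bm

# a synthetic community: 24 species with disc ranges on a 1000 km landscape,
# occupancy decaying at range margins, 10% of species unreachable
cfg = bm.CommunityConfig(n_species=24, n_sites=96, n_visits=4, seed=1)
sim = bm.simulate_community(cfg)

spec = bm.ModelSpec.bmsom()                       # intercepts + elev + distance
spec.det_terms = [bm.Term("time", random=False)]  # time-of-day on detection
bundle = bm.build_covariate_bundle(sim.ranges, sim.sites, spec,
                                   visit_times=sim.visit_times)
model = bm.OccupancyModel(sim.history, bundle, spec)
res = model.fit(chains=2, warmup=400, draws=400, seed=2)
print(res.convergence_report())
# convergence PASS: max r-hat 1.0213 (limit 1.03), divergences 0,
# min E-BFMI 0.682 (limit 0.2)
print(res.summary().loc[["mu_a", "mu_occ_distance", "sigma_occ_distance"]]
      [["mean", "sd", "q5", "q95"]].round(2))
#                     mean    sd    q5   q95
# parameter
# mu_a                0.53  0.19  0.22  0.83
# mu_occ_distance    -3.35  0.46 -4.11 -2.60
# sigma_occ_distance  1.84  0.35  1.33  2.48
```

The distance-slope population mean and SD (truth −3.5 and 1.6 in this
simulation) are recovered within posterior uncertainty; `mu_a` is core-range
occupancy on the logit scale because the distance covariate is ~0 there.

Model comparison against the traditional MSOM on the same data:

```python
spec_m = bm.ModelSpec.msom(); spec_m.det_terms = [bm.Term("time", random=False)]
bundle_m = bm.build_covariate_bundle(sim.ranges, sim.sites, spec_m,
                                     visit_times=sim.visit_times)
res_m = bm.OccupancyModel(sim.history, bundle_m, spec_m).fit(
    chains=2, warmup=400, draws=400, seed=3)
comp = bm.elpd_compare(bm.loo(res.pointwise_loglik()),
                       bm.loo(res_m.pointwise_loglik()))
print(comp)
# ELPD difference 92.3 (SE 13.2)
```

The range-covariate model wins by ~7 standard errors; `comp.per_species`
breaks the difference down per species and
`bm.plot_elpd_comparison(comp, "fig.png")` renders the dot-and-interval
chart.  `bm.richness_profile(res)` returns per-site posterior richness
(median and 80% interval), including the never-observed species.

A command-line pipeline wraps the same steps
(`bmsom simulate | covariates | clip | fit | loo | predict | run`); `bmsom
run --config cfg.yaml --out-dir out` executes the declared stages and writes
a manifest with seeds and file hashes.  The data-augmentation comparison is
reproduced by `python examples/data_augmentation_demo.py`.

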