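"""Posterior prediction: occupancy surfaces, conditional occupancy, richness.

Point-scale species richness is predicted by summing, over all species the
range information admits at a site, the posterior probability that the
species is truly present given its detection history — including species
never detected anywhere.  This is the quantity behind elevational richness
profiles, and the place where a traditional data-augmented model and the
range-covariate model can be compared head to head.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "occupancy_surface",
    "conditional_occupancy",
    "richness_profile",
    "pasture_effect_table",
]


def occupancy_surface(
    results,
    bundle_new,
    mode: str = "clipped",
    mask_new=None,
    quantiles=(0.05, 0.95),
    thin: int = 1,
):
    """Posterior occupancy probabilities at prediction points.

    ``bundle_new`` must be built with the training scaling constants
    (``build_covariate_bundle(..., reuse_scaling=training_bundle.scaling)``).
    ``mode='clipped'`` zeroes cells removed by ``mask_new`` (structural
    zeros); ``mode='projected'`` pushes the coefficients everywhere.

    Returns a dict with ``mean`` (S, J_new) and ``q<p>`` quantile surfaces.
    """
    if mode not in ("clipped", "projected"):
        raise ValueError("mode must be 'clipped' or 'projected'")
    if mode == "clipped" and mask_new is None:
        raise ValueError("clipped mode needs a prediction-point clip mask")
    train_scaling = results.model.bundle.scaling
    if train_scaling and bundle_new.scaling != train_scaling:
        raise ValueError(
            "prediction covariates were not built with the training scaling "
            "constants; pass reuse_scaling=training_bundle.scaling"
        )
    from .model import linear_predictors

    spec = results.model.spec
    lay = results.model.layout
    flat = results.flat_draws()[::thin]
    D = flat.shape[0]
    S, J = bundle_new.n_species, bundle_new.n_sites
    psis = np.empty((D, S, J))
    for d, v in enumerate(flat):
        p = lay.unpack(v)
        psi, _ = linear_predictors(p, bundle_new, spec, n_visits=1)
        psis[d] = psi
    if mode == "clipped":
        psis = psis * mask_new.retained[None, :, :]
    out = {"mean": psis.mean(axis=0)}
    for q in quantiles:
        out[f"q{int(100 * q)}"] = np.quantile(psis, q, axis=0)
    return out


def conditional_occupancy(psi, theta, y, visit_mask=None):
    """P(Z = 1 | detection history) for one cell, vectorized over leading axes.

    Any detection forces Z = 1; an all-zero history gives the Bayes posterior
    ``psi prod_k (1-theta_k) / (psi prod_k (1-theta_k) + 1 - psi)``.

    ``psi``: (...,), ``theta``/``y``/``visit_mask``: (..., K).
    """
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y)
    if visit_mask is None:
        visit_mask = np.ones(y.shape, bool)
    visit_mask = np.broadcast_to(np.asarray(visit_mask, bool), y.shape)
    theta = np.broadcast_to(theta, y.shape)
    detected = (y * visit_mask).sum(axis=-1) > 0
    with np.errstate(divide="ignore"):
        log_miss = np.where(visit_mask, np.log1p(-theta), 0.0).sum(axis=-1)
    num = psi * np.exp(log_miss)
    cond = num / (num + 1.0 - psi)
    return np.where(detected, 1.0, cond)


def richness_profile(
    results,
    mode: str = "expectation",
    subset: str = "all",
    quantiles=(0.1, 0.9),
    thin: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior point-scale richness per site.

    Per draw and site, sums conditional occupancy (``mode='expectation'``)
    or a Bernoulli realization of it (``mode='bernoulli'``) over retained
    species.  ``subset='never_observed'`` keeps only species with all-zero
    detection histories.  For a data-augmented model, pseudospecies
    contributions are weighted by their posterior inclusion probability.

    Returns a frame with site_id, median and the requested quantiles.
    """
    if mode not in ("expectation", "bernoulli"):
        raise ValueError("mode must be 'expectation' or 'bernoulli'")
    if subset not in ("all", "never_observed"):
        raise ValueError("subset must be 'all' or 'never_observed'")
    model = results.model
    rng = np.random.default_rng(seed)
    flat = results.flat_draws()[::thin]
    D = flat.shape[0]
    S, J, K = model.S, model.J, model.K
    keep_sp = np.ones(S, bool)
    if subset == "never_observed":
        keep_sp = ~model.observed_flag
    rich = np.zeros((D, J))
    for d, v in enumerate(flat):
        psi, theta = model.predictors(v)
        cond = conditional_occupancy(psi, theta, model.y, model.V)
        cond = cond * model.R  # removed cells are structural zeros
        if model.spec.is_augmented:
            q = _inclusion_probability(model, v)
            cond = cond * q[:, None]
        cond = cond[keep_sp]
        if mode == "bernoulli":
            rich[d] = (rng.uniform(size=cond.shape) < cond).sum(axis=0)
        else:
            rich[d] = cond.sum(axis=0)
    out = {"site_id": model.history.site_ids, "median": np.median(rich, axis=0)}
    for q in quantiles:
        out[f"q{int(100 * q)}"] = np.quantile(rich, q, axis=0)
    return pd.DataFrame(out)


def _inclusion_probability(model, v):
    """Per-species posterior probability of community membership at one draw."""
    from scipy.special import expit

    q = np.ones(model.S)
    t_om = model.layout.get(v, "logit_omega")
    omega = float(expit(t_om))
    cell = model._cell_loglik_matrix(v)
    sp_sum = cell.sum(axis=1)
    un = ~model.observed_flag
    mix = np.logaddexp(np.log1p(-omega), np.log(omega) + sp_sum[un])
    q[un] = np.exp(np.log(omega) + sp_sum[un] - mix)
    return q


def pasture_effect_table(results, term: str = "habitat") -> pd.DataFrame:
    """Per-species posterior of the land-use occupancy contrast.

    The contrast is the logit-scale difference in occupancy between the two
    land-use classes (the named covariate is coded 0/1, so the contrast is
    minus the species' total slope: positive values mean higher occupancy in
    the reference class).  Fixed and species random components are summed;
    never-observed species shrink toward the population mean.
    """
    spec = results.model.spec
    names = {t.name: t for t in spec.occ_terms}
    if term not in names:
        raise ValueError(f"model has no land-use term {term!r}")
    t = names[term]
    if t.random:
        draws = results.posterior(f"slope_occ_{term}")  # (chains, draws, S)
        contrast = -draws.reshape(-1, draws.shape[-1])
    else:
        d = results.posterior(f"b_{term}").reshape(-1)
        contrast = -np.repeat(d[:, None], results.model.S, axis=1)
    return pd.DataFrame(
        {
            "species_id": results.model.species_ids,
            "median": np.median(contrast, axis=0),
            "q5": np.quantile(contrast, 0.05, axis=0),
            "q95": np.quantile(contrast, 0.95, axis=0),
            "observed": results.model.observed_flag,
        }
    )
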