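"""Approximate leave-one-out cross-validation by Pareto-smoothed importance sampling.

The expected log pointwise predictive density (ELPD) of each species-site
cell is estimated from posterior draws by importance sampling, with the upper
tail of the importance ratios stabilized by a fitted generalized Pareto
distribution (PSIS, Vehtari et al.).  The tail-shape estimate k-hat flags
cells where the approximation is unreliable (k-hat > 0.7); such cells are
re-evaluated by an exact leave-one-cell-out refit when a refit hook is
supplied, and flagged otherwise.

The leave-one-out unit is the species-site detection-history vector: visits
within a cell share the latent occupancy state, so leaving out single visits
would violate the conditional-independence assumption behind the importance
weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .results import PointwiseLogLik

logger = logging.getLogger(__name__)

KHAT_THRESHOLD = 0.7


def psis_smooth(log_ratios: np.ndarray):
    """Pareto-smooth one cell's importance ratios.

    Fits a generalized Pareto distribution to the largest
    ``ceil(min(0.2 S, 3 sqrt(S)))`` ratios, replaces them by expected order
    statistics, truncates and self-normalizes.  Returns
    ``(normalized weights, k-hat)``.  Identical ratios carry no tail
    information: the sentinel k-hat of −inf and uniform weights are returned.
    """
    lr = np.asarray(log_ratios, dtype=float)
    if lr.ndim != 1:
        raise ValueError("log_ratios must be a vector of draws")
    if lr.size < 100:
        raise ValueError("PSIS needs at least 100 draws")
    if np.ptp(lr) < 1e-12:
        return np.full(lr.size, 1.0 / lr.size), -np.inf
    lw, k = az.psislw(lr)
    lw = np.asarray(lw)
    return np.exp(lw), float(k)


@dataclass
class LooResult:
    """PSIS-LOO estimate: total ELPD, its SE, and per-cell detail."""

    elpd_total: float
    se_total: float
    pointwise: np.ndarray       # (n_cells,) elpd_i
    pareto_k: np.ndarray        # (n_cells,)
    cell_species: np.ndarray
    cell_sites: np.ndarray
    n_refits: int = 0
    flagged: np.ndarray | None = None   # high-k cells not refit

    @property
    def n_cells(self) -> int:
        return self.pointwise.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.cell_species,
                "site_id": self.cell_sites,
                "elpd": self.pointwise,
                "pareto_k": self.pareto_k,
            }
        )


def loo(pointwise: PointwiseLogLik, refit_hook=None) -> LooResult:
    """PSIS-LOO from a matrix of per-draw, per-cell log-likelihoods.

    ``refit_hook(cell_index) -> float`` should return the exact leave-one-out
    elpd of a cell (from a refit without it); it is invoked for cells whose
    Pareto k-hat exceeds 0.7.
    """
    ll = np.asarray(pointwise.values, dtype=float)
    if not np.isfinite(ll).all():
        raise ValueError("non-finite pointwise log-likelihoods")
    S_draws, n = ll.shape
    elpd = np.empty(n)
    khat = np.empty(n)
    for i in range(n):
        lr = -ll[:, i]
        if np.ptp(lr) < 1e-12:
            # constant likelihood across draws: weights uniform, elpd exact
            elpd[i] = logsumexp(ll[:, i]) - np.log(S_draws)
            khat[i] = -np.inf
            continue
        lw, k = az.psislw(lr)
        elpd[i] = logsumexp(np.asarray(lw) + ll[:, i])
        khat[i] = float(k)
    high = khat > KHAT_THRESHOLD
    n_refits = 0
    flagged = np.zeros(n, bool)
    if high.any():
        if refit_hook is not None:
            for i in np.nonzero(high)[0]:
                elpd[i] = float(refit_hook(i))
                n_refits += 1
        else:
            flagged = high
            logger.warning(
                "%d cells with Pareto k-hat > %.1f and no refit hook",
                int(high.sum()), KHAT_THRESHOLD,
            )
    se = float(np.sqrt(n * np.var(elpd, ddof=0)))
    return LooResult(
        elpd_total=float(elpd.sum()),
        se_total=se,
        pointwise=elpd,
        pareto_k=khat,
        cell_species=np.asarray(pointwise.cell_species),
        cell_sites=np.asarray(pointwise.cell_sites),
        n_refits=n_refits,
        flagged=flagged,
    )


@dataclass
class ElpdComparison:
    """Pairwise predictive comparison (first model minus second)."""

    elpd_diff: float
    se_diff: float
    pointwise_diff: np.ndarray
    per_species: pd.DataFrame   # columns: species_id, elpd_diff, se, n_cells

    def __str__(self) -> str:
        return f"ELPD difference {self.elpd_diff:.1f} (SE {self.se_diff:.1f})"


def elpd_compare(a: LooResult, b: LooResult) -> ElpdComparison:
    """Overall and per-species ELPD differences (a minus b) with SEs.

    Both results must cover the identical cell set — comparisons involving a
    clipped model must be restricted to the cells retained after clipping
    before fitting, or via :func:`restrict_to_common_cells`.
    """
    key_a = list(zip(a.cell_species.tolist(), a.cell_sites.tolist()))
    key_b = list(zip(b.cell_species.tolist(), b.cell_sites.tolist()))
    if key_a != key_b:
        raise ValueError(
            "cell sets differ between the two results; restrict both to the "
            "intersection of retained cells (restrict_to_common_cells)"
        )
    d = a.pointwise - b.pointwise
    n = d.size
    rows = []
    for sp in pd.unique(a.cell_species):
        sel = a.cell_species == sp
        ds = d[sel]
        rows.append(
            {
                "species_id": sp,
                "elpd_diff": float(ds.sum()),
                "se": float(np.sqrt(ds.size * np.var(ds, ddof=0))),
                "n_cells": int(ds.size),
            }
        )
    return ElpdComparison(
        elpd_diff=float(d.sum()),
        se_diff=float(np.sqrt(n * np.var(d, ddof=0))),
        pointwise_diff=d,
        per_species=pd.DataFrame(rows),
    )


def restrict_to_common_cells(p: PointwiseLogLik, q: PointwiseLogLik):
    """Subset both pointwise matrices to their common species-site cells."""
    key_p = list(zip(p.cell_species.tolist(), p.cell_sites.tolist()))
    key_q = list(zip(q.cell_species.tolist(), q.cell_sites.tolist()))
    common = set(key_p) & set(key_q)
    ip = [i for i, k in enumerate(key_p) if k in common]
    iq = [i for i, k in enumerate(key_q) if k in common]
    sub = lambda x, idx: PointwiseLogLik(
        values=x.values[:, idx],
        cell_species=x.cell_species[idx],
        cell_sites=x.cell_sites[idx],
    )
    return sub(p, ip), sub(q, iq)


def make_refit_hook(results, **fit_kwargs):
    """Exact leave-one-cell-out refit hook for :func:`loo`.

    Returns a callable mapping a cell index (into the retained-cell ordering
    of ``results.pointwise_loglik()``) to the exact elpd of that cell: the
    model is refit with the cell removed from the likelihood and the cell's
    predictive density averaged over the refit posterior.
    """
    from .clipping import ClipMask, RETAINED, REASON_GEOGRAPHIC
    from .model import OccupancyModel

    model = results.model
    keep = model.R > 0
    s_idx, j_idx = np.nonzero(keep)
    defaults = dict(chains=2, warmup=300, draws=300, seed=0)
    defaults.update(fit_kwargs)

    def hook(i: int) -> float:
        si, sj = int(s_idx[i]), int(j_idx[i])
        retained = keep.copy()
        retained[si, sj] = False
        reason = np.where(retained, RETAINED, REASON_GEOGRAPHIC).astype(np.int8)
        # carry visit-level structure through
        vmask = model.mask.visit_mask if model.mask is not None else None
        mask = ClipMask(retained, reason, visit_mask=vmask)
        if model.history.y[si, sj].any():
            # cell has detections: removing it from the mask would trip the
            # omission check, so blank the data instead of clipping
            hist = model.history
            y2 = hist.y.copy()
            vm2 = hist.visit_mask.copy()
            y2[si, sj] = 0
            from .data import DetectionHistory

            hist2 = DetectionHistory(y2, vm2, hist.species_ids, hist.site_ids)
            sub = OccupancyModel(hist2, model.bundle, model.spec, mask=mask)
        else:
            sub = OccupancyModel(model.history, model.bundle, model.spec, mask=mask)
        res = sub.fit(**defaults)
        flat = res.flat_draws()
        vals = np.empty(flat.shape[0])
        for d, v in enumerate(flat):
            # evaluate the held-out cell's likelihood under the refit posterior
            cl = _heldout_cell_loglik(model, v, si, sj)
            vals[d] = cl
        return float(logsumexp(vals) - np.log(vals.size))

    return hook


def _heldout_cell_loglik(model, v, si, sj):
    """Marginal log-likelihood of one cell at one (unconstrained) draw."""
    from .model import cell_loglik

    psi, theta = model.predictors(v)
    vm = model.history.visit_mask[si, sj]
    return cell_loglik(psi[si, sj], theta[si, sj], model.history.y[si, sj], vm)


def plot_elpd_comparison(comp: ElpdComparison, path=None, ax=None):
    """Per-species ELPD-difference dot-and-interval chart (±2 SE lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = comp.per_species.sort_values("elpd_diff", ascending=False).reset_index(
        drop=True
    )
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    xs = np.arange(len(tab))
    ax.errorbar(
        xs, tab["elpd_diff"], yerr=2 * tab["se"], fmt="o", ms=3, lw=1, capsize=0
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("species (ordered by ELPD difference)")
    ax.set_ylabel("ELPD difference ± 2 SE")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return ax
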