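"""Posterior results: draws, convergence diagnostics, pointwise predictive density.

`OccupancyResults` is the object returned by :meth:`OccupancyModel.fit`; it
owns the raw unconstrained draws plus sampler metadata and exposes constrained
parameter arrays, a summary table, the convergence report enforcing the
fitting criteria (max rank-normalized split r-hat < 1.03, zero divergences,
E-BFMI > 0.2 in every chain), and the per-cell log-likelihood matrix that
feeds leave-one-out model comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

RHAT_LIMIT = 1.03
EBFMI_LIMIT = 0.2


@dataclass
class ConvergenceReport:
    passed: bool
    max_rhat: float
    n_divergent: int
    min_ebfmi: float
    table: pd.DataFrame

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"convergence {status}: max r-hat {self.max_rhat:.4f} "
            f"(limit {RHAT_LIMIT}), divergences {self.n_divergent}, "
            f"min E-BFMI {self.min_ebfmi:.3f} (limit {EBFMI_LIMIT})"
        )

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "max_rhat": float(self.max_rhat),
            "n_divergent": int(self.n_divergent),
            "min_ebfmi": float(self.min_ebfmi),
        }


@dataclass
class PointwiseLogLik:
    """Per-draw, per-retained-cell log predictive densities.

    The prediction unit is the species-site detection-history vector (visits
    within a cell share the latent Z, so the cell is the exchangeable unit
    for leave-one-out cross-validation).
    """

    values: np.ndarray          # (n_total_draws, n_cells)
    cell_species: np.ndarray    # (n_cells,) species ids
    cell_sites: np.ndarray      # (n_cells,) site ids

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


class OccupancyResults:
    """Posterior of a fitted multi-species occupancy model."""

    def __init__(self, model, draws: np.ndarray, chain_stats: list):
        # draws: (chains, n_draws, dim) unconstrained
        self.model = model
        self.draws = draws
        self.chain_stats = chain_stats

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def n_divergent(self) -> int:
        return sum(st.n_divergent for st in self.chain_stats)

    # -- parameter access ---------------------------------------------------------

    def flat_draws(self) -> np.ndarray:
        """(chains * draws, dim) unconstrained draws."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior(self, name: str) -> np.ndarray:
        """Constrained posterior draws of a named quantity.

        Recognized names: hyperparameters (``mu_a``, ``sigma_a``, ``mu_c``,
        ``sigma_c``, ``rho``, ``omega``), per-species vectors (``a``, ``c``),
        slope hyperparameters (``mu_occ_<term>``, ``sigma_occ_<term>`` and the
        detection analogues), per-species slope vectors (``slope_occ_<term>``,
        ``slope_det_<term>``) and fixed coefficients (``b_<term>``,
        ``d_<term>``).
        """
        lay = self.model.layout
        v = self.draws
        g = lambda n: lay.get(v, n)
        if name in ("mu_a", "mu_c", "u_rho"):
            return np.asarray(g(name))
        if name == "sigma_a":
            return np.exp(g("log_sigma_a"))
        if name == "sigma_c":
            return np.exp(g("log_sigma_c"))
        if name == "rho":
            return np.tanh(g("u_rho"))
        if name == "omega":
            from scipy.special import expit

            return expit(g("logit_omega"))
        if name == "a":
            return g("mu_a")[..., None] + np.exp(g("log_sigma_a"))[..., None] * g("z_a")
        if name == "c":
            rho = np.tanh(g("u_rho"))[..., None]
            dev = rho * g("z_a") + np.sqrt(1 - rho**2) * g("z_c")
            return g("mu_c")[..., None] + np.exp(g("log_sigma_c"))[..., None] * dev
        for pref in ("occ", "det"):
            if name == f"mu_{pref}" or name.startswith(f"mu_{pref}_"):
                return np.asarray(g(name))
            if name.startswith(f"sigma_{pref}_"):
                term = name[len(f"sigma_{pref}_"):]
                return np.exp(g(f"log_sigma_{pref}_{term}"))
            if name.startswith(f"slope_{pref}_"):
                term = name[len(f"slope_{pref}_"):]
                mu = g(f"mu_{pref}_{term}")[..., None]
                sd = np.exp(g(f"log_sigma_{pref}_{term}"))[..., None]
                return mu + sd * g(f"z_{pref}_{term}")
        if name in lay.slices:
            return np.asarray(g(name))
        raise KeyError(f"unknown parameter {name!r}")

    def scalar_parameter_names(self) -> list:
        names = ["mu_a", "sigma_a", "mu_c", "sigma_c", "rho"]
        for t in self.model.spec.occ_terms:
            if t.random:
                names += [f"mu_occ_{t.name}", f"sigma_occ_{t.name}"]
            else:
                names.append(f"b_{t.name}")
        for t in self.model.spec.det_terms:
            if t.random:
                names += [f"mu_det_{t.name}", f"sigma_det_{t.name}"]
            else:
                names.append(f"d_{t.name}")
        if self.model.spec.is_augmented:
            names.append("omega")
        return names

    def to_inference_data(self) -> az.InferenceData:
        post = {}
        for name in self.scalar_parameter_names():
            post[name] = self.posterior(name)
        post["a"] = self.posterior("a")
        post["c"] = self.posterior("c")
        for t in self.model.spec.occ_terms:
            if t.random:
                post[f"slope_occ_{t.name}"] = self.posterior(f"slope_occ_{t.name}")
        for t in self.model.spec.det_terms:
            if t.random:
                post[f"slope_det_{t.name}"] = self.posterior(f"slope_det_{t.name}")
        sample_stats = {
            "energy": np.stack([st.energy for st in self.chain_stats]),
            "diverging": np.stack([st.divergent for st in self.chain_stats]),
        }
        return az.from_dict(posterior=post, sample_stats=sample_stats)

    # -- summaries & diagnostics ---------------------------------------------------

    def summary(self, quantiles=(0.05, 0.95)) -> pd.DataFrame:
        """Posterior summary of the scalar parameters (mean, sd, quantiles,
        rank-normalized split r-hat and bulk ESS)."""
        rows = []
        two_plus = self.n_chains >= 2
        for name in self.scalar_parameter_names():
            d = self.posterior(name)
            row = {
                "parameter": name,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
            }
            for q in quantiles:
                row[f"q{int(100 * q)}"] = float(np.quantile(d, q))
            if two_plus:
                row["rhat"] = float(_rhat(d))
                row["ess_bulk"] = float(_ess(d))
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def convergence_report(self) -> ConvergenceReport:
        """Enforce the fitting criteria; requires at least two chains."""
        if self.n_chains < 2:
            raise ValueError(
                "r-hat is undefined for a single chain; rerun with chains >= 2"
            )
        rows = []
        # diagnose every unconstrained coordinate plus derived scalars
        lay = self.model.layout
        for name, sl in lay.slices.items():
            block = self.draws[:, :, sl]
            for k in range(block.shape[-1]):
                d = block[:, :, k]
                label = name if block.shape[-1] == 1 else f"{name}[{k}]"
                rows.append((label, _rhat(d), _ess(d)))
        table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk"])
        max_rhat = float(table["rhat"].max())
        ebfmi = [float(e) for e in _ebfmi_per_chain(self.chain_stats)]
        min_ebfmi = min(ebfmi)
        n_div = self.n_divergent
        passed = (max_rhat < RHAT_LIMIT) and (n_div == 0) and (min_ebfmi > EBFMI_LIMIT)
        return ConvergenceReport(passed, max_rhat, n_div, min_ebfmi, table)

    # -- predictive quantities -----------------------------------------------------

    def pointwise_loglik(self, thin: int = 1) -> PointwiseLogLik:
        """Marginal log-likelihood of every retained cell at every draw."""
        model = self.model
        if model.spec.is_augmented:
            raise NotImplementedError(
                "pointwise predictive densities are defined for the non-augmented "
                "variants (cells are not independent under the Omega mixture)"
            )
        flat = self.flat_draws()[::thin]
        keep = model.R > 0
        s_idx, j_idx = np.nonzero(keep)
        vals = np.empty((flat.shape[0], s_idx.size))
        for d, v in enumerate(flat):
            cl = model._cell_loglik_matrix(v)
            vals[d] = cl[s_idx, j_idx]
        return PointwiseLogLik(
            values=vals,
            cell_species=np.asarray([model.species_ids[i] for i in s_idx]),
            cell_sites=np.asarray([model.history.site_ids[j] for j in j_idx]),
        )

    def psi_theta_draws(self, thin: int = 1):
        """(psi (D,S,J), theta (D,S,J,K)) across flattened draws."""
        flat = self.flat_draws()[::thin]
        D = flat.shape[0]
        model = self.model
        psi = np.empty((D, model.S, model.J))
        theta = np.empty((D, model.S, model.J, model.K))
        for d, v in enumerate(flat):
            psi[d], theta[d] = model.predictors(v)
        return psi, theta

    # -- persistence ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flat draws with chain/draw indices and named columns."""
        lay = self.model.layout
        cols = {}
        chains, ndraws, _ = self.draws.shape
        cols["chain"] = np.repeat(np.arange(chains), ndraws)
        cols["draw"] = np.tile(np.arange(ndraws), chains)
        for name, sl in lay.slices.items():
            width = sl.stop - sl.start
            block = self.draws[:, :, sl].reshape(-1, width)
            if width == 1:
                cols[name] = block[:, 0]
            else:
                for k in range(width):
                    cols[f"{name}[{k}]"] = block[:, k]
        return pd.DataFrame(cols)


# -- diagnostics helpers (rank-normalized split r-hat, bulk ESS, E-BFMI) --------


def _rhat(d: np.ndarray) -> float:
    """Rank-normalized split r-hat of a (chains, draws) array via arviz."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(np.asarray(d), method="rank")
        return float(r["x"].values if hasattr(r, "keys") else r)


def _ess(d: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.ess(np.asarray(d), method="bulk")
        return float(r["x"].values if hasattr(r, "keys") else r)


def _ebfmi_per_chain(chain_stats) -> np.ndarray:
    """Energy fraction of missing information, one value per chain."""
    out = []
    for st in chain_stats:
        e = np.asarray(st.energy, dtype=float)
        de = np.diff(e)
        denom = np.var(e)
        out.append(np.mean(de**2) / denom if denom > 0 else np.nan)
    return np.asarray(out)
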