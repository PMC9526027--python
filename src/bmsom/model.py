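"""Multi-species occupancy models with the latent occupancy state marginalized.

The likelihood for species *i*, site *j*, visit *k* is

    Y_ijk ~ Bernoulli(Z_ij * theta_ijk)
    Z_ij  ~ Bernoulli(psi_ij)
    logit psi   = a + X b        (occupancy)
    logit theta = c + W d        (detection)

with species-level random intercepts for both occupancy and detection
(correlated), optional species-specific random slopes (notably for the range
covariates of the biogeographic variant), and fixed coefficients.  The
discrete Z is summed out analytically,

    P(y_ij.) = psi_ij * prod_k theta^y (1-theta)^(1-y)
               + (1 - psi_ij) * 1{sum_k y = 0},

so the joint log density is smooth and gradient-based samplers apply.  Z is
recovered post hoc by :func:`bmsom.predict.conditional_occupancy`.

The data-augmented variant (Dorazio & Royle) appends all-zero pseudospecies,
each a member of the community with probability Omega; their species-level
likelihood is the Omega-mixture of "absent" and "present but never detected".

`OccupancyModel` follows the statsmodels convention: construct from data,
call :meth:`OccupancyModel.fit` to obtain an
:class:`~bmsom.results.OccupancyResults`.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, log_expit

from .clipping import ClipMask, validate_mask_against_detections
from .covariates import CovariateBundle
from .data import DetectionHistory

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "Priors",
    "ModelSpec",
    "ParameterVector",
    "OccupancyModel",
    "cell_loglik",
    "linear_predictors",
    "dataset_logprob",
    "augmented_cell_logprob",
]


@dataclass(frozen=True)
class Term:
    """One named covariate term; ``random`` means species-specific slopes."""

    name: str
    random: bool = True


@dataclass
class Priors:
    """Weakly-informative default priors, overridable per model.

    Population means and fixed coefficients get Normal(0, mu_scale);
    hierarchical standard deviations get Half-Normal(0, sd_scale); the
    occupancy/detection intercept correlation is uniform on (-1, 1); the
    data-augmentation inclusion probability Omega is uniform on (0, 1).
    """

    mu_scale: float = 2.5
    sd_scale: float = 2.0
    coef_scale: float = 2.5


@dataclass
class ModelSpec:
    """Declarative model description: terms, random-effects structure, priors.

    Species random intercepts for occupancy and detection (correlated) are
    always present — the minimum random-effects structure of a multi-species
    occupancy model.
    """

    occ_terms: list = field(default_factory=list)
    det_terms: list = field(default_factory=list)
    variant: str = "msom"              # msom | bmsom | data_augmented
    distance_scale_km: float = 200.0
    priors: Priors = field(default_factory=Priors)
    n_pseudospecies: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("msom", "bmsom", "data_augmented"):
            raise ValueError(f"unknown variant {self.variant!r}")
        self.occ_terms = [t if isinstance(t, Term) else Term(**t) for t in self.occ_terms]
        self.det_terms = [t if isinstance(t, Term) else Term(**t) for t in self.det_terms]
        if self.variant == "data_augmented" and self.n_pseudospecies <= 0:
            raise ValueError("data_augmented variant needs n_pseudospecies > 0")
        names = [t.name for t in self.occ_terms] + [t.name for t in self.det_terms]
        if len(set([t.name for t in self.occ_terms])) != len(self.occ_terms):
            raise ValueError("duplicate occupancy terms")
        if len(set([t.name for t in self.det_terms])) != len(self.det_terms):
            raise ValueError("duplicate detection terms")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def msom(cls, elev_slope: bool = True, **kw) -> "ModelSpec":
        """Traditional MSOM: correlated intercepts + random elevation slope."""
        occ = [Term("elev")] if elev_slope else []
        return cls(occ_terms=occ, variant="msom", **kw)

    @classmethod
    def bmsom(
        cls,
        elev_slope: bool = True,
        distance: bool = True,
        std_elev: bool = False,
        std_elev_quadratic: bool = False,
        distance_scale_km: float = 200.0,
        **kw,
    ) -> "ModelSpec":
        """Biogeographic MSOM: adds range covariates with random slopes."""
        occ = []
        if elev_slope:
            occ.append(Term("elev"))
        if distance:
            occ.append(Term("distance"))
        if std_elev:
            occ.append(Term("std_elev"))
        if std_elev_quadratic:
            occ.append(Term("std_elev2"))
        return cls(
            occ_terms=occ,
            variant="bmsom",
            distance_scale_km=distance_scale_km,
            **kw,
        )

    @classmethod
    def data_augmented(
        cls, n_pseudospecies: int = 1000, elev_slope: bool = True,
        elev_quadratic: bool = False, **kw
    ) -> "ModelSpec":
        """Data-augmented MSOM: pseudospecies, no species-specific covariates.

        Only site-level covariates (raw elevation, optionally its square) are
        allowed, because pseudospecies have no range or trait information.
        """
        occ = []
        if elev_slope:
            occ.append(Term("elev"))
        if elev_quadratic:
            occ.append(Term("elev2"))
        return cls(
            occ_terms=occ,
            variant="data_augmented",
            n_pseudospecies=n_pseudospecies,
            **kw,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = Priors(**d["priors"])
        return cls(**d)

    @property
    def is_augmented(self) -> bool:
        return self.variant == "data_augmented"


@dataclass
class ParameterVector:
    """Constrained, named parameter values (used by simulators and oracles).

    ``occ_random``/``det_random`` map term name -> per-species slope vector;
    ``occ_fixed``/``det_fixed`` map term name -> scalar coefficient.
    Hyperparameters are optional: they only matter when prior terms are
    evaluated.
    """

    a: np.ndarray
    c: np.ndarray
    occ_random: dict = field(default_factory=dict)
    occ_fixed: dict = field(default_factory=dict)
    det_random: dict = field(default_factory=dict)
    det_fixed: dict = field(default_factory=dict)
    mu_a: float = 0.0
    sigma_a: float = 1.0
    mu_c: float = 0.0
    sigma_c: float = 1.0
    rho: float = 0.0
    slope_hypers: dict = field(default_factory=dict)  # name -> (mu, sigma)
    omega: float | None = None

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if self.sigma_a <= 0 or self.sigma_c <= 0:
            raise ValueError("standard deviations must be > 0")
        if not -1 < self.rho < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if self.omega is not None and not 0 < self.omega < 1:
            raise ValueError("omega must lie in (0, 1)")


# ---------------------------------------------------------------------------
# spec-level operations (scalar/matrix forms used directly in tests & oracles)
# ---------------------------------------------------------------------------

def cell_loglik(psi, theta, y, visit_mask=None):
    """Marginal log-probability of one species-site detection history.

    log[ psi * prod_k theta_k^y_k (1-theta_k)^(1-y_k) + (1-psi) 1{sum y = 0} ]
    computed on the log scale.  ``theta`` and ``y`` are visit vectors;
    ``visit_mask`` excludes visits that did not happen.  An empty (fully
    masked) history has probability one.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    theta = np.broadcast_to(np.atleast_1d(np.asarray(theta, dtype=float)), y.shape)
    if visit_mask is None:
        visit_mask = np.ones_like(y, dtype=bool)
    else:
        visit_mask = np.atleast_1d(np.asarray(visit_mask, dtype=bool))
    y = y[visit_mask]
    theta = theta[visit_mask]
    psi = float(psi)
    any_det = y.sum() > 0
    if psi == 0.0:
        if any_det:
            warnings.warn("detection with psi = 0: impossible history")
            return -np.inf
        return 0.0
    with np.errstate(divide="ignore"):
        det_ll = np.sum(y * np.log(theta) + (1 - y) * np.log1p(-theta))
    log_a = np.log(psi) + det_ll
    if any_det:
        return float(log_a)
    if psi == 1.0:
        return float(log_a)
    return float(np.logaddexp(log_a, np.log1p(-psi)))


def augmented_cell_logprob(omega, all_zero_logliks, species_observed):
    """Species-level log-probability under data augmentation.

    Observed species: ``log(omega) + sum_j cell_loglik`` (its detections prove
    membership).  Never-observed (pseudo)species: the Omega-mixture
    ``log[(1-omega) + omega * exp(sum_j all-zero cell_loglik)]``.
    """
    if not 0 < omega <= 1:
        raise ValueError("omega must lie in (0, 1]")
    total = float(np.sum(all_zero_logliks))
    if species_observed:
        return float(np.log(omega) + total)
    if omega == 1.0:
        return total
    return float(np.logaddexp(np.log1p(-omega), np.log(omega) + total))


def linear_predictors(
    params: ParameterVector, bundle: CovariateBundle, spec: ModelSpec,
    n_visits: int = 1
):
    """(psi (S,J), theta (S,J,K)) from named parameters and design data."""
    S, J = bundle.n_species, bundle.n_sites
    eta = np.broadcast_to(params.a[:, None], (S, J)).copy()
    for t in spec.occ_terms:
        kind, x = bundle.occ_column(t.name)
        if not np.isfinite(np.asarray(x)).all():
            raise ValueError(f"non-finite covariate {t.name!r}")
        if t.random:
            sl = np.atleast_1d(np.asarray(params.occ_random[t.name], dtype=float))
            contrib = sl[:, None] * (x[None, :] if kind == "site" else x)
        else:
            contrib = params.occ_fixed[t.name] * (
                x[None, :] if kind == "site" else x
            )
        eta = eta + contrib
    K = n_visits
    for w in bundle.det_visit.values():
        K = np.asarray(w).shape[1]
    zeta = np.broadcast_to(params.c[:, None, None], (S, J, K)).copy()
    for t in spec.det_terms:
        w = np.asarray(bundle.det_visit[t.name], dtype=float)
        if t.random:
            sl = np.atleast_1d(np.asarray(params.det_random[t.name], dtype=float))
            zeta = zeta + sl[:, None, None] * w[None, :, :]
        else:
            zeta = zeta + params.det_fixed[t.name] * w[None, :, :]
    return expit(eta), expit(zeta)


def dataset_logprob(
    params: ParameterVector,
    bundle: CovariateBundle,
    history: DetectionHistory,
    mask: ClipMask | None,
    spec: ModelSpec,
    include_prior: bool = True,
):
    """Joint log density of the dataset at fixed parameter values.

    Sum of marginalized cell log-likelihoods over retained cells, plus (by
    default) the hierarchical prior terms.  Refuses to evaluate while the
    clip mask removes cells containing detections.
    """
    model = OccupancyModel(history, bundle, spec, mask=mask)
    v = model.layout.pack(params)
    ll = model.loglike(v, include_prior=False)
    if include_prior:
        ll += model._log_prior(v)[0]
    return float(ll)


# ---------------------------------------------------------------------------
# parameter layout: unconstrained sampling vector <-> named parameters
# ---------------------------------------------------------------------------


class ParamLayout:
    """Slices of the flat unconstrained vector the sampler works on.

    Layout: [mu_a, mu_c, log_sigma_a, log_sigma_c, atanh_rho,
             z_a (S), z_c (S),
             per occupancy random term: mu, log_sigma, z (S),
             per occupancy fixed term: coefficient,
             per detection random term: mu, log_sigma, z (S),
             per detection fixed term: coefficient,
             (data-augmented only) logit_omega]

    Species random effects use the non-centered parameterization with the
    (a, c) intercept pair sharing a Cholesky-correlated bivariate deviation.
    """

    def __init__(self, spec: ModelSpec, n_species: int):
        self.spec = spec
        self.S = n_species
        self.slices: dict[str, slice] = {}
        pos = 0

        def add(name, size):
            nonlocal pos
            self.slices[name] = slice(pos, pos + size)
            pos += size

        for nm in ("mu_a", "mu_c", "log_sigma_a", "log_sigma_c", "u_rho"):
            add(nm, 1)
        add("z_a", self.S)
        add("z_c", self.S)
        for t in spec.occ_terms:
            if t.random:
                add(f"mu_occ_{t.name}", 1)
                add(f"log_sigma_occ_{t.name}", 1)
                add(f"z_occ_{t.name}", self.S)
            else:
                add(f"b_{t.name}", 1)
        for t in spec.det_terms:
            if t.random:
                add(f"mu_det_{t.name}", 1)
                add(f"log_sigma_det_{t.name}", 1)
                add(f"z_det_{t.name}", self.S)
            else:
                add(f"d_{t.name}", 1)
        if spec.is_augmented:
            add("logit_omega", 1)
        self.dim = pos

    def get(self, v: np.ndarray, name: str):
        s = self.slices[name]
        out = v[..., s]
        return out[..., 0] if s.stop - s.start == 1 else out

    def pack(self, p: ParameterVector) -> np.ndarray:
        """Named constrained parameters -> unconstrained vector."""
        S = self.S
        a = np.asarray(p.a, dtype=float)
        c = np.asarray(p.c, dtype=float)
        if a.shape != (S,) or c.shape != (S,):
            raise ValueError(f"intercept vectors must have length {S}")
        v = np.zeros(self.dim)
        rho = p.rho
        sr = np.sqrt(1 - rho**2)
        z_a = (a - p.mu_a) / p.sigma_a
        z_c = ((c - p.mu_c) / p.sigma_c - rho * z_a) / sr
        vals = {
            "mu_a": p.mu_a,
            "mu_c": p.mu_c,
            "log_sigma_a": np.log(p.sigma_a),
            "log_sigma_c": np.log(p.sigma_c),
            "u_rho": np.arctanh(rho),
            "z_a": z_a,
            "z_c": z_c,
        }
        for t in self.spec.occ_terms:
            if t.random:
                mu, sd = p.slope_hypers.get(t.name, (0.0, 1.0))
                sl = np.asarray(p.occ_random[t.name], dtype=float)
                vals[f"mu_occ_{t.name}"] = mu
                vals[f"log_sigma_occ_{t.name}"] = np.log(sd)
                vals[f"z_occ_{t.name}"] = (sl - mu) / sd
            else:
                vals[f"b_{t.name}"] = p.occ_fixed[t.name]
        for t in self.spec.det_terms:
            if t.random:
                mu, sd = p.slope_hypers.get(t.name, (0.0, 1.0))
                sl = np.asarray(p.det_random[t.name], dtype=float)
                vals[f"mu_det_{t.name}"] = mu
                vals[f"log_sigma_det_{t.name}"] = np.log(sd)
                vals[f"z_det_{t.name}"] = (sl - mu) / sd
            else:
                vals[f"d_{t.name}"] = p.det_fixed[t.name]
        if self.spec.is_augmented:
            if p.omega is None:
                raise ValueError("data-augmented model needs omega")
            vals["logit_omega"] = np.log(p.omega) - np.log1p(-p.omega)
        for name, val in vals.items():
            v[self.slices[name]] = val
        return v

    def unpack(self, v: np.ndarray) -> ParameterVector:
        """Unconstrained vector -> named constrained parameters."""
        g = lambda n: self.get(v, n)
        sigma_a = np.exp(g("log_sigma_a"))
        sigma_c = np.exp(g("log_sigma_c"))
        rho = np.tanh(g("u_rho"))
        sr = np.sqrt(1 - rho**2)
        z_a, z_c = g("z_a"), g("z_c")
        a = g("mu_a") + sigma_a * z_a
        c = g("mu_c") + sigma_c * (rho * z_a + sr * z_c)
        occ_r, occ_f, det_r, det_f, hyp = {}, {}, {}, {}, {}
        for t in self.spec.occ_terms:
            if t.random:
                mu = g(f"mu_occ_{t.name}")
                sd = np.exp(g(f"log_sigma_occ_{t.name}"))
                occ_r[t.name] = mu + sd * g(f"z_occ_{t.name}")
                hyp[t.name] = (float(mu), float(sd))
            else:
                occ_f[t.name] = float(g(f"b_{t.name}"))
        for t in self.spec.det_terms:
            if t.random:
                mu = g(f"mu_det_{t.name}")
                sd = np.exp(g(f"log_sigma_det_{t.name}"))
                det_r[t.name] = mu + sd * g(f"z_det_{t.name}")
                hyp[t.name] = (float(mu), float(sd))
            else:
                det_f[t.name] = float(g(f"d_{t.name}"))
        omega = None
        if self.spec.is_augmented:
            omega = float(expit(g("logit_omega")))
        return ParameterVector(
            a=a, c=c, occ_random=occ_r, occ_fixed=occ_f, det_random=det_r,
            det_fixed=det_f, mu_a=float(g("mu_a")), sigma_a=float(sigma_a),
            mu_c=float(g("mu_c")), sigma_c=float(sigma_c), rho=float(rho),
            slope_hypers=hyp, omega=omega,
        )


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------


class OccupancyModel:
    """Joint posterior density of an (b)MSOM, ready for gradient-based MCMC.

    Parameters
    ----------
    history : DetectionHistory for the observed species.
    bundle : CovariateBundle whose species axis matches ``history``.
    spec : ModelSpec.
    mask : optional ClipMask; removed cells are structural zeros outside the
        likelihood.  Construction fails if any removed cell contains a
        detection (a range-map error of omission to be fixed upstream).
    """

    def __init__(
        self,
        history: DetectionHistory,
        bundle: CovariateBundle,
        spec: ModelSpec,
        mask: ClipMask | None = None,
    ):
        if list(bundle.species_ids) != list(history.species_ids):
            raise ValueError("bundle and history species orderings differ")
        if list(bundle.site_ids) != list(history.site_ids):
            raise ValueError("bundle and history site orderings differ")
        self.history = history
        self.bundle = bundle
        self.spec = spec
        S_obs, J, K = history.y.shape

        if mask is not None:
            violations = validate_mask_against_detections(mask, history)
            if violations:
                raise ValueError(
                    "clip mask removes cells containing detections (range-map "
                    f"errors of omission): {violations[:10]}"
                )
        self.mask = mask

        if spec.is_augmented:
            for t in spec.occ_terms:
                kind, _ = bundle.occ_column(t.name)
                if kind == "species_site":
                    raise ValueError(
                        "data-augmented models cannot use species-specific "
                        f"covariates (term {t.name!r})"
                    )
            n_pseudo = spec.n_pseudospecies
        else:
            n_pseudo = 0
        self.n_pseudo = n_pseudo
        self.n_observed = S_obs
        S = S_obs + n_pseudo
        self.S, self.J, self.K = S, J, K

        y = np.zeros((S, J, K))
        y[:S_obs] = history.y
        V = np.ones((S, J, K), bool)
        V[:S_obs] = history.visit_mask
        R = np.ones((S, J), bool)
        if mask is not None:
            R[:S_obs] = mask.retained
            if mask.visit_mask is not None:
                V[:S_obs] &= mask.visit_mask
        V &= R[:, :, None]
        y = np.where(V, y, 0.0)
        self.y, self.V, self.R = y, V, R.astype(float)
        self.anyobs = (y > 0).any(axis=2)
        self.observed_flag = np.zeros(S, bool)
        self.observed_flag[:S_obs] = history.detected_anywhere()

        # design data, expanded to the augmented species set
        self._occ_design = []   # (name, random, kind, array)
        for t in spec.occ_terms:
            kind, x = bundle.occ_column(t.name)
            x = np.asarray(x, dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite covariate {t.name!r}")
            self._occ_design.append((t.name, t.random, kind, x))
        self._det_design = []
        for t in spec.det_terms:
            w = np.asarray(bundle.det_visit[t.name], dtype=float)
            if not np.isfinite(w).all():
                raise ValueError(f"non-finite covariate {t.name!r}")
            self._det_design.append((t.name, t.random, w))
        self._det_varying = len(self._det_design) > 0
        if not self._det_varying:
            # sufficient statistics for the intercept-only detection fast path
            self.n1 = (y * V).sum(axis=2)
            self.n0 = ((1 - y) * V).sum(axis=2)

        self.layout = ParamLayout(spec, S)
        self.species_ids = list(history.species_ids) + [
            f"pseudo_{i+1:04d}" for i in range(n_pseudo)
        ]
        self._prior_index = self._build_prior_index()

        # stacked design tensors for the fused gradient kernel
        T = len(self._occ_design)
        self._C = np.zeros((T, S, J))
        for t, (_, _, kind, x) in enumerate(self._occ_design):
            self._C[t] = x[None, :] if kind == "site" else x
        Td = len(self._det_design)
        self._Wd = np.zeros((Td, J, K))
        for t, (_, _, w) in enumerate(self._det_design):
            self._Wd[t] = w


    def _build_prior_index(self):
        lay = self.layout
        mu, logsig, z, coef = [], [], [], []
        for name, sl in lay.slices.items():
            idx = list(range(sl.start, sl.stop))
            if name.startswith("mu_"):
                mu += idx
            elif name.startswith("log_sigma_"):
                logsig += idx
            elif name.startswith("z_"):
                z += idx
            elif name.startswith(("b_", "d_")):
                coef += idx
        return {
            "mu": np.asarray(mu, int),
            "logsig": np.asarray(logsig, int),
            "z": np.asarray(z, int),
            "coef": np.asarray(coef, int),
        }

    # -- linear predictors -------------------------------------------------------

    def predictors(self, v: np.ndarray):
        """psi (S,J) and theta (S,J,K) at an unconstrained parameter vector."""
        eta, zeta = self._predictor_logits(v)
        theta = expit(np.broadcast_to(zeta, (self.S, self.J, self.K)))
        return expit(eta), theta

    def _predictor_logits(self, v: np.ndarray):
        lay = self.layout
        g = lambda n: lay.get(v, n)
        sigma_a = np.exp(g("log_sigma_a"))
        sigma_c = np.exp(g("log_sigma_c"))
        rho = np.tanh(g("u_rho"))
        sr = np.sqrt(1 - rho**2)
        z_a, z_c = g("z_a"), g("z_c")
        a = g("mu_a") + sigma_a * z_a
        c = g("mu_c") + sigma_c * (rho * z_a + sr * z_c)
        eta = np.repeat(a[:, None], self.J, axis=1)
        for name, random, kind, x in self._occ_design:
            if random:
                sl = g(f"mu_occ_{name}") + np.exp(g(f"log_sigma_occ_{name}")) * g(
                    f"z_occ_{name}"
                )
                eta += sl[:, None] * (x[None, :] if kind == "site" else x)
            else:
                eta += g(f"b_{name}") * (x[None, :] if kind == "site" else x)
        if self._det_varying:
            zeta = np.repeat(c[:, None, None], self.J, axis=1) * np.ones(
                (1, 1, self.K)
            )
            for name, random, w in self._det_design:
                if random:
                    sl = g(f"mu_det_{name}") + np.exp(
                        g(f"log_sigma_det_{name}")
                    ) * g(f"z_det_{name}")
                    zeta += sl[:, None, None] * w[None, :, :]
                else:
                    zeta += g(f"d_{name}") * w[None, :, :]
        else:
            zeta = c[:, None, None]
        return eta, zeta

    # -- log density and gradient --------------------------------------------------

    def loglike(self, v: np.ndarray, include_prior: bool = False) -> float:
        lp, _ = self._logp_grad(v, need_grad=False, include_prior=include_prior)
        return lp

    def logp(self, v: np.ndarray) -> float:
        """Posterior log density (likelihood + priors) up to a constant."""
        return self.loglike(v, include_prior=True)

    def logp_and_grad(self, v: np.ndarray):
        return self._logp_grad(v, need_grad=True, include_prior=True)

    def cell_logliks(self, v: np.ndarray) -> np.ndarray:
        """Per-cell marginalized log-likelihoods (S, J); removed cells NaN."""
        cl = self._cell_loglik_matrix(v)
        return np.where(self.R > 0, cl, np.nan)

    def _cell_loglik_matrix(self, v):
        eta, zeta = self._predictor_logits(v)
        log_psi = log_expit(eta)
        log_1mpsi = log_expit(-eta)
        if self._det_varying:
            log_t = log_expit(zeta)
            log_1mt = log_expit(-zeta)
            det_sum = ((self.y * log_t + (1 - self.y) * log_1mt) * self.V).sum(axis=2)
        else:
            lt = log_expit(zeta[:, :, 0] if zeta.ndim == 3 else zeta)
            l1t = log_expit(-(zeta[:, :, 0] if zeta.ndim == 3 else zeta))
            det_sum = self.n1 * lt + self.n0 * l1t
        log_a = log_psi + det_sum
        cell = np.where(self.anyobs, log_a, np.logaddexp(log_a, log_1mpsi))
        return cell * self.R

    def _logp_grad(self, v, need_grad=True, include_prior=True):
        lay = self.layout
        S = self.S
        g = lambda n: lay.get(v, n)
        mu_a, mu_c = g("mu_a"), g("mu_c")
        sigma_a = np.exp(g("log_sigma_a"))
        sigma_c = np.exp(g("log_sigma_c"))
        rho = np.tanh(g("u_rho"))
        sr = np.sqrt(1 - rho**2)
        z_a, z_c = g("z_a"), g("z_c")
        a = mu_a + sigma_a * z_a
        c = mu_c + sigma_c * (rho * z_a + sr * z_c)

        occ_info, det_info = [], []
        T, Td = len(self._occ_design), len(self._det_design)
        so = np.empty((T, S))
        for t, (name, random, kind, x) in enumerate(self._occ_design):
            if random:
                sd_r = np.exp(g(f"log_sigma_occ_{name}"))
                so[t] = g(f"mu_occ_{name}") + sd_r * g(f"z_occ_{name}")
                occ_info.append((name, True, sd_r))
            else:
                so[t] = g(f"b_{name}")
                occ_info.append((name, False, None))
        sd_arr = np.empty((Td, S))
        for t, (name, random, w) in enumerate(self._det_design):
            if random:
                sd_r = np.exp(g(f"log_sigma_det_{name}"))
                sd_arr[t] = g(f"mu_det_{name}") + sd_r * g(f"z_det_{name}")
                det_info.append((name, True, sd_r))
            else:
                sd_arr[t] = g(f"d_{name}")
                det_info.append((name, False, None))

        from ._kernels import fused_logp_grad

        ll, cell, grad_a, grad_c, grad_so, grad_sd = fused_logp_grad(
            np.ascontiguousarray(a), np.ascontiguousarray(c), so, self._C,
            sd_arr, self._Wd, self.y, self.V, self.anyobs, self.R,
        )

        if self.spec.is_augmented:
            t_om = g("logit_omega")
            omega = expit(t_om)
            log_om = log_expit(t_om)
            log_1mom = log_expit(-t_om)
            sp_sum = (cell * self.R).sum(axis=1)
            obs = self.observed_flag
            mix = np.logaddexp(log_1mom, log_om + sp_sum[~obs])
            ll = (log_om + sp_sum[obs]).sum() + mix.sum()

        if not np.isfinite(ll):
            if not need_grad:
                return -np.inf, None
            return -np.inf, np.zeros(lay.dim)

        if not need_grad and not include_prior:
            return float(ll), None

        lp = float(ll)
        grad = np.zeros(lay.dim) if need_grad else None

        if need_grad:
            if self.spec.is_augmented:
                # gradients are linear in the cell weight: rescale per species
                q = np.ones(S)
                q[~self.observed_flag] = np.exp(
                    log_om + sp_sum[~self.observed_flag] - mix
                )
                grad_a = grad_a * q
                grad_c = grad_c * q
                grad_so = grad_so * q[None, :]
                grad_sd = grad_sd * q[None, :]

            def acc(name, val):
                grad[lay.slices[name]] += val

            for t, (name, random, sd_r) in enumerate(occ_info):
                per_sp = grad_so[t]
                if random:
                    acc(f"mu_occ_{name}", per_sp.sum())
                    acc(
                        f"log_sigma_occ_{name}",
                        (per_sp * g(f"z_occ_{name}")).sum() * sd_r,
                    )
                    acc(f"z_occ_{name}", per_sp * sd_r)
                else:
                    acc(f"b_{name}", per_sp.sum())
            for t, (name, random, sd_r) in enumerate(det_info):
                per_sp = grad_sd[t]
                if random:
                    acc(f"mu_det_{name}", per_sp.sum())
                    acc(
                        f"log_sigma_det_{name}",
                        (per_sp * g(f"z_det_{name}")).sum() * sd_r,
                    )
                    acc(f"z_det_{name}", per_sp * sd_r)
                else:
                    acc(f"d_{name}", per_sp.sum())

            # chain rule into intercept hyperparameters (non-centered)
            acc("mu_a", grad_a.sum())
            acc("mu_c", grad_c.sum())
            acc("log_sigma_a", (grad_a * z_a).sum() * sigma_a)
            acc("log_sigma_c", (grad_c * (rho * z_a + sr * z_c)).sum() * sigma_c)
            acc("z_a", grad_a * sigma_a + grad_c * sigma_c * rho)
            acc("z_c", grad_c * sigma_c * sr)
            # (d c / d u) = sigma_c * (z_a (1 - rho^2) - rho * sr * z_c); the
            # rho/sr form is unstable as |rho| -> 1
            acc(
                "u_rho",
                (grad_c * sigma_c * (z_a * (1 - rho**2) - rho * sr * z_c)).sum(),
            )
            if self.spec.is_augmented:
                es = np.exp(sp_sum[~self.observed_flag])
                d_omega = (es - 1.0) / np.exp(mix)
                total_domega = self.observed_flag.sum() / omega + d_omega.sum()
                acc("logit_omega", total_domega * omega * (1 - omega))

        if include_prior:
            plp, pgrad = self._log_prior(v)
            lp += plp
            if need_grad:
                grad += pgrad
        return lp, grad

    def _log_prior(self, v):
        """Log prior + transform Jacobians, and its gradient (vectorized)."""
        pr = self.spec.priors
        idx = self._prior_index
        lay = self.layout
        grad = np.zeros(lay.dim)

        mu = v[idx["mu"]]
        lp = -0.5 * np.sum(mu**2) / pr.mu_scale**2
        grad[idx["mu"]] = -mu / pr.mu_scale**2

        ls = v[idx["logsig"]]
        s2 = np.exp(2.0 * ls)
        lp += np.sum(-0.5 * s2 / pr.sd_scale**2 + ls)
        grad[idx["logsig"]] = -s2 / pr.sd_scale**2 + 1.0

        z = v[idx["z"]]
        lp += -0.5 * np.sum(z**2)
        grad[idx["z"]] = -z

        if idx["coef"].size:
            b = v[idx["coef"]]
            lp += -0.5 * np.sum(b**2) / pr.coef_scale**2
            grad[idx["coef"]] = -b / pr.coef_scale**2

        u = v[lay.slices["u_rho"]][0]
        rho = np.tanh(u)
        with np.errstate(divide="ignore"):
            # -inf when tanh saturates: correctly rejects |rho| -> 1
            lp += np.log1p(-(rho**2))   # Jacobian of rho = tanh(u); flat prior
        grad[lay.slices["u_rho"]] = -2.0 * rho

        if self.spec.is_augmented:
            t = v[lay.slices["logit_omega"]][0]
            om = expit(t)
            lp += log_expit(t) + log_expit(-t)  # Jacobian; flat prior on omega
            grad[lay.slices["logit_omega"]] = 1.0 - 2.0 * om
        return float(lp), grad

    # -- fitting -------------------------------------------------------------------

    def fit(
        self,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.9,
        max_treedepth: int = 10,
        jitter: float = 0.1,
    ):
        """Sample the posterior by the No-U-Turn sampler; returns OccupancyResults."""
        from .results import OccupancyResults
        from .sampler import nuts_sample

        if chains < 1:
            raise ValueError("chains must be >= 1")
        if chains == 1:
            warnings.warn(
                "single chain: convergence diagnostics (r-hat) will be unavailable"
            )
        rng = np.random.default_rng(seed)
        all_draws, all_stats = [], []
        for ch in range(chains):
            chain_rng = np.random.default_rng(rng.integers(2**31 - 1))
            x0 = self._initial_point(chain_rng, jitter)
            lp0, _ = self.logp_and_grad(x0)
            if not np.isfinite(lp0):
                raise ValueError(
                    f"non-finite initial log-probability ({lp0}) at chain {ch}"
                )
            d, st = nuts_sample(
                self.logp_and_grad,
                x0,
                warmup,
                draws,
                chain_rng,
                target_accept=target_accept,
                max_treedepth=max_treedepth,
            )
            all_draws.append(d)
            all_stats.append(st)
        return OccupancyResults(self, np.stack(all_draws), all_stats)

    def _initial_point(self, rng, jitter):
        # prior means (zeros on the unconstrained scale) with a small jitter
        return jitter * rng.uniform(-1.0, 1.0, self.layout.dim)
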