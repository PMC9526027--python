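"""Synthetic multi-species communities with biogeographic structure.

The generator emulates the situation the biogeographic occupancy model is
built for: a survey region crossed by many species' range margins, occupancy
decaying at those margins through a scaled inverse-logit distance covariate
with species-specific slopes, a 1-D elevational gradient with
species-specific elevational limits, correlated species-level occupancy and
detection intercepts, visit-level detection heterogeneity (time of day), and
a pool of species whose ranges lie so far from every site that they can never
be observed.

Ranges are discs (centroid + radius) in a flat projected plane, so the signed
distance to the range margin has the closed form ``|p - centre| - radius``
and every geometric quantity downstream can be checked against it exactly.
The generative link functions are the fitted model's (logit), so parameter
recovery is well-posed by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point

from .covariates import scaled_inverse_logit, standardize_elevation
from .data import DetectionHistory, RangeInfo, SimulationTruth

#: vertices per quarter-circle when discretizing disc ranges for GeoJSON export
DISC_QUAD_SEGS = 256


@dataclass
class CommunityConfig:
    """Generative settings for one synthetic community.

    Defaults describe the reference study design used throughout the test
    suite: a 1000 x 1000 km landscape, two dozen species with ~500 km-radius
    disc ranges (large relative to the 200 km transform scale, so range cores
    reach the transform's zero asymptote), occupancy decaying at range margins on a 200 km scale, and a
    tenth of the species pool placed too far away ever to be detected.
    """

    n_species: int = 24
    n_sites: int = 96
    n_visits: int = 4
    extent_km: tuple = (1000.0, 1000.0)
    # range geometry: disc centroids uniform over the landscape, lognormal radii
    radius_km_log_mean: float = math.log(500.0)
    radius_km_log_sd: float = 0.3
    # elevational structure
    elev_range_m: tuple = (0.0, 3000.0)
    # optional Beta(a, b) shape for site elevations over elev_range_m
    # (uneven sampling effort along the gradient); None = uniform
    elev_beta_params: tuple | None = None
    elev_limit_mid_m: tuple = (800.0, 2200.0)
    elev_breadth_log_mean: float = math.log(1200.0)
    elev_breadth_log_sd: float = 0.3
    # intercept hyperparameters (logit scale)
    mu_a: float = 0.5
    sigma_a: float = 0.8
    mu_c: float = 0.0
    sigma_c: float = 0.8
    rho_ac: float = 0.5
    # random slope hyperparameters
    mu_beta_elev: float = 0.0
    sigma_beta_elev: float = 0.5
    mu_beta_dist: float = -3.5
    sigma_beta_dist: float = 1.6
    # optional quadratic decay in species-standardized elevation (1-D designs)
    include_std_elev_quadratic: bool = False
    mu_beta_selev2: float = -2.0
    sigma_beta_selev2: float = 0.5
    # detection: visit-level time-of-day effect (hours post-sunrise, standardized)
    det_time_coef: float = -0.3
    # covariate construction
    distance_scale_km: float = 200.0
    include_distance: bool = True
    # never-observable pool: centroids placed >= 3 radii beyond the site hull
    frac_never_observable: float = 0.1
    # seasonal windows (day-of-year) for a migratory fraction; residents get none
    frac_migratory: float = 0.0
    season_window: tuple = (91, 212)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2 (occupancy needs repeat visits)")
        if self.n_species < 1 or self.n_sites < 1:
            raise ValueError("need at least one species and one site")
        for nm in ("sigma_a", "sigma_c", "sigma_beta_elev", "sigma_beta_dist",
                   "sigma_beta_selev2"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not -1 <= self.rho_ac <= 1:
            raise ValueError("rho_ac must lie in [-1, 1]")
        if self.extent_km[0] <= 0 or self.extent_km[1] <= 0:
            raise ValueError("zero sites inside any landscape: degenerate extent")
        if not 0 <= self.frac_never_observable < 1:
            raise ValueError("frac_never_observable must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        d = dict(d)
        for k in ("extent_km", "elev_range_m", "elev_limit_mid_m", "season_window",
                  "elev_beta_params"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SimulatedCommunity:
    """Everything one replicate produces: data, ranges, sites and the truth."""

    history: DetectionHistory
    ranges: list
    sites: pd.DataFrame
    truth: SimulationTruth
    visit_doy: np.ndarray      # (J, K) day-of-year of each visit
    visit_times: np.ndarray    # (J, K) hours post-sunrise

    def __iter__(self):  # tuple-style unpacking: history, ranges, sites, truth
        return iter((self.history, self.ranges, self.sites, self.truth))


def simulate_community(
    config: CommunityConfig, replicate: int = 0
) -> SimulatedCommunity:
    """Draw one community and its detection data; deterministic given seed.

    One RNG stream per replicate, seeded from ``config.seed + replicate``.
    """
    rng = np.random.default_rng(config.seed + replicate)
    S, J, K = config.n_species, config.n_sites, config.n_visits
    ex, ey = config.extent_km

    # --- sites ------------------------------------------------------------------
    x = rng.uniform(0, ex, J)
    y = rng.uniform(0, ey, J)
    lo_e, hi_e = config.elev_range_m
    if config.elev_beta_params is not None:
        ab = config.elev_beta_params
        elev_m = lo_e + (hi_e - lo_e) * rng.beta(ab[0], ab[1], J)
    else:
        elev_m = rng.uniform(lo_e, hi_e, J)
    base_doy = rng.integers(150, 171, J)
    visit_doy = base_doy[:, None] + np.arange(K)[None, :]
    visit_times = rng.uniform(0.0, 5.0, (J, K))
    sites = pd.DataFrame(
        {
            "site_id": [f"s{j+1:04d}" for j in range(J)],
            "x_km": x,
            "y_km": y,
            "elev_m": elev_m,
            "date": [
                (pd.Timestamp("2018-01-01") + pd.Timedelta(days=int(d) - 1)).date().isoformat()
                for d in base_doy
            ],
        }
    )

    # --- species ranges -----------------------------------------------------------
    radius = np.exp(
        rng.normal(config.radius_km_log_mean, config.radius_km_log_sd, S)
    )
    if np.any(radius <= 0):
        raise ValueError("degenerate (zero-area) range drawn")
    n_never = int(round(config.frac_never_observable * S))
    never_idx = rng.choice(S, size=n_never, replace=False) if n_never else np.array([], int)
    centre = np.column_stack([rng.uniform(0, ex, S), rng.uniform(0, ey, S)])
    half_diag = 0.5 * math.hypot(ex, ey)
    mid = np.array([ex / 2.0, ey / 2.0])
    for i in never_idx:
        ang = rng.uniform(0, 2 * math.pi)
        # nearest site is then >= 4 radii from the centroid: >= 3 radii past the margin
        dist = half_diag + 4.0 * radius[i]
        centre[i] = mid + dist * np.array([math.cos(ang), math.sin(ang)])

    mid_elev = rng.uniform(*config.elev_limit_mid_m, S)
    breadth = np.exp(
        rng.normal(config.elev_breadth_log_mean, config.elev_breadth_log_sd, S)
    )
    if config.include_std_elev_quadratic:
        # 1-D designs: the unreachable pool lives above the sampled gradient
        # (every site >= 3 standardized units below the species' lower limit)
        for i in never_idx:
            mid_elev[i] = config.elev_range_m[1] + 1.5 * breadth[i]
    elev_lower = mid_elev - breadth / 2.0
    elev_upper = mid_elev + breadth / 2.0

    n_mig = int(round(config.frac_migratory * S))
    mig_idx = set(rng.choice(S, size=n_mig, replace=False).tolist()) if n_mig else set()

    ranges = []
    for i in range(S):
        season = config.season_window if i in mig_idx else (None, None)
        ranges.append(
            RangeInfo(
                species_id=f"sp{i+1:03d}",
                geometry=Point(*centre[i]).buffer(radius[i], quad_segs=DISC_QUAD_SEGS),
                elev_lower_m=float(elev_lower[i]),
                elev_upper_m=float(elev_upper[i]),
                season_start=season[0],
                season_end=season[1],
            )
        )

    # --- true covariates (closed forms for disc ranges) ----------------------------
    d_signed = (
        np.hypot(x[None, :] - centre[:, 0, None], y[None, :] - centre[:, 1, None])
        - radius[:, None]
    )
    d_cov = scaled_inverse_logit(d_signed, config.distance_scale_km)
    s_elev = standardize_elevation(
        elev_m[None, :], elev_lower[:, None], elev_upper[:, None]
    )
    elev_sd = elev_m.std()
    elev_site = (elev_m - elev_m.mean()) / (elev_sd if elev_sd > 0 else 1.0)

    # --- parameters -----------------------------------------------------------------
    # correlated intercept pair via its Cholesky factor (degenerate sds allowed)
    z1 = rng.standard_normal(S)
    z2 = rng.standard_normal(S)
    rho = config.rho_ac
    a = config.mu_a + config.sigma_a * z1
    c = config.mu_c + config.sigma_c * (rho * z1 + math.sqrt(1 - rho**2) * z2)
    beta_elev = rng.normal(config.mu_beta_elev, config.sigma_beta_elev, S)
    beta_dist = (
        rng.normal(config.mu_beta_dist, config.sigma_beta_dist, S)
        if config.include_distance
        else np.zeros(S)
    )

    eta = a[:, None] + beta_elev[:, None] * elev_site[None, :]
    if config.include_distance:
        eta = eta + beta_dist[:, None] * d_cov
    hyper_extra = {}
    if config.include_std_elev_quadratic:
        beta_selev2 = rng.normal(config.mu_beta_selev2, config.sigma_beta_selev2, S)
        eta = eta + beta_selev2[:, None] * s_elev**2
        hyper_extra["beta_selev2"] = beta_selev2
    psi = expit(eta)

    t_sd = visit_times.std()
    times_std = (visit_times - visit_times.mean()) / (t_sd if t_sd > 0 else 1.0)
    theta = expit(c[:, None, None] + config.det_time_coef * times_std[None, :, :])

    # --- latent states and data ------------------------------------------------------
    z = (rng.uniform(size=(S, J)) < psi).astype(np.int8)
    ydraw = (rng.uniform(size=(S, J, K)) < theta).astype(np.int8)
    yobs = z[:, :, None] * ydraw
    history = DetectionHistory(
        y=yobs,
        visit_mask=np.ones((S, J, K), bool),
        species_ids=[r.species_id for r in ranges],
        site_ids=sites["site_id"].tolist(),
    )

    truth = SimulationTruth(
        a=a,
        c=c,
        beta_elev=beta_elev,
        beta_dist=beta_dist,
        psi=psi,
        theta=np.broadcast_to(theta, (S, J, K)).copy(),
        z=z,
        signed_distance_km=d_signed,
        distance_covariate=d_cov,
        std_elevation=s_elev,
        elev_site=elev_site,
        hyperparams={
            "mu_a": config.mu_a, "sigma_a": config.sigma_a,
            "mu_c": config.mu_c, "sigma_c": config.sigma_c,
            "rho_ac": config.rho_ac,
            "mu_beta_elev": config.mu_beta_elev,
            "sigma_beta_elev": config.sigma_beta_elev,
            "mu_beta_dist": config.mu_beta_dist,
            "sigma_beta_dist": config.sigma_beta_dist,
            "det_time_coef": config.det_time_coef,
            "radius_km": radius,
            "centre_km": centre,
            "times_std": times_std,
            **hyper_extra,
        },
    )
    return SimulatedCommunity(history, ranges, sites, truth, visit_doy, visit_times)


def make_never_observed_pool(
    truth: SimulationTruth, history: DetectionHistory
) -> list:
    """Species ids with all-zero detection histories.

    Partitions the community into observed / never-observed, mirroring the
    observed-plus-never-observed species pools of real biogeographic surveys.
    """
    detected = history.detected_anywhere()
    return [sid for sid, d in zip(history.species_ids, detected) if not d]
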