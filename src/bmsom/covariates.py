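"""Range covariates: turning range maps and elevational limits into model inputs.

The central idea of the biogeographic multi-species occupancy model is that
preexisting range information enters the occupancy regression as ordinary
covariates with species-specific random slopes.  Two covariates are built
here:

* a **geographic** covariate — the inverse logit of the signed distance from a
  survey point to the species' range margin, expressed in units of a scale
  parameter (e.g. 200 km).  It asymptotes at 0 deep inside the range (so the
  hierarchical intercepts describe core-range occupancy) and at 1 far outside.
* an **elevational** covariate — the point elevation linearly rescaled per
  species so that the species' upper range limit maps to +1 and the lower
  limit to −1; an optional quadratic term captures mid-range optima.

The module also contains the empirical diagnostic used to choose the distance
scale: bin species-site combinations by distance to the range edge and pick
the scale whose transform most nearly linearises the logit of the naive
occupancy proportion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .data import DetectionHistory, RangeInfo, validate_site_table

__all__ = [
    "signed_distance_to_range",
    "signed_distance_matrix",
    "scaled_inverse_logit",
    "standardize_elevation",
    "linearization_diagnostic",
    "CovariateBundle",
    "build_covariate_bundle",
]


def signed_distance_to_range(
    site_xy: tuple[float, float],
    rng_info: RangeInfo,
    ignore_boundary: BaseGeometry | None = None,
) -> float:
    """Signed distance (km) from a point to a species' range margin.

    Negative inside the range, positive outside, 0 exactly on the boundary.
    ``ignore_boundary`` optionally removes boundary segments (e.g. shorelines)
    from the nearest-edge search; the sign is still determined by containment.
    """
    if rng_info.geometry is None or rng_info.geometry.is_empty:
        raise ValueError(f"species {rng_info.species_id}: empty range geometry")
    geom = rng_info.geometry
    pt = Point(*site_xy)
    inside = geom.covers(pt)
    if ignore_boundary is None:
        d = geom.boundary.distance(pt) if inside else geom.distance(pt)
    else:
        boundary = geom.boundary.difference(ignore_boundary)
        if boundary.is_empty:
            raise ValueError(
                f"species {rng_info.species_id}: ignore-boundary layer removed "
                "the entire range margin"
            )
        d = boundary.distance(pt)
    return -d if inside else d


def signed_distance_matrix(
    ranges: list[RangeInfo], sites: pd.DataFrame, ignore_boundary=None
) -> np.ndarray:
    """(n_species, n_sites) signed distances for every species-site pair."""
    sites = validate_site_table(sites)
    out = np.empty((len(ranges), len(sites)))
    xy = list(zip(sites["x_km"].to_numpy(), sites["y_km"].to_numpy()))
    for i, r in enumerate(ranges):
        for j, p in enumerate(xy):
            out[i, j] = signed_distance_to_range(p, r, ignore_boundary)
    return out


def scaled_inverse_logit(distance_km, scale_km):
    """``1 / (1 + exp(-d/s))`` — the geographic range covariate transform.

    Strictly increasing in distance, 0.5 at the range margin, asymptoting at 0
    in the range core and 1 far out of range.
    """
    scale_km = np.asarray(scale_km, dtype=float)
    if np.any(scale_km <= 0):
        raise ValueError("scale_km must be > 0")
    return expit(np.asarray(distance_km, dtype=float) / scale_km)


def standardize_elevation(elev_m, lower_m, upper_m):
    """Linear map sending the species' lower limit to −1 and upper limit to +1."""
    lower_m = np.asarray(lower_m, dtype=float)
    upper_m = np.asarray(upper_m, dtype=float)
    if np.any(lower_m >= upper_m):
        raise ValueError("lower_m must be < upper_m")
    return (2.0 * np.asarray(elev_m, dtype=float) - (upper_m + lower_m)) / (
        upper_m - lower_m
    )


def unstandardize_elevation(s, lower_m, upper_m):
    """Inverse of :func:`standardize_elevation`."""
    return (np.asarray(s) * (upper_m - lower_m) + (upper_m + lower_m)) / 2.0


def linearization_diagnostic(
    history: DetectionHistory,
    distances: np.ndarray,
    candidate_scales: list[float],
    n_bins: int = 20,
):
    """Choose the distance-transform scale that linearises occupancy decay.

    Species-site combinations are binned by their distance to the range edge
    (equal-width bins over the observed span).  Per bin, a naive occupancy
    proportion (fraction of cells with at least one detection) is computed,
    with an empirical-logit half-count correction where the proportion is 0 or
    1.  For each candidate scale the logit-proportion is regressed on the
    transformed bin midpoint and scored by the count-weighted coefficient of
    determination; the best (largest R², ties broken toward the smallest
    scale) is returned.

    Returns
    -------
    (table, selected_scale) : table is a DataFrame with columns
        ``scale_km`` and ``linearity_r2`` plus a ``all_scores_equal`` attr.
    """
    if not candidate_scales:
        raise ValueError("need at least one candidate scale")
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (history.n_species, history.n_sites):
        raise ValueError("distances must be (n_species, n_sites)")
    occupied = history.detected_anywhere_by_cell()
    d = distances.ravel()
    occ = occupied.ravel()
    lo, hi = d.min(), d.max()
    if not hi > lo:
        raise ValueError("insufficient occupancy variation: degenerate distance span")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    mids, props, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        k = int(occ[sel].sum())
        if k == 0 or k == n:
            p = (k + 0.5) / (n + 1.0)  # empirical-logit correction
        else:
            p = k / n
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        props.append(p)
        counts.append(n)
    if len(mids) < 2:
        raise ValueError("insufficient occupancy variation: fewer than 2 usable bins")
    mids = np.asarray(mids)
    yv = logit(np.asarray(props))
    w = np.asarray(counts, dtype=float)
    scores = []
    for s in candidate_scales:
        x = expit(mids / float(s))
        scores.append(_weighted_r2(x, yv, w))
    scores = np.asarray(scores)
    table = pd.DataFrame({"scale_km": candidate_scales, "linearity_r2": scores})
    all_equal = bool(np.allclose(scores, scores[0]))
    table.attrs["all_scores_equal"] = all_equal
    if all_equal:
        selected = float(min(candidate_scales))
    else:
        best = scores.max()
        tied = [s for s, r in zip(candidate_scales, scores) if r >= best - 1e-12]
        selected = float(min(tied))
    return table, selected


def _weighted_r2(x, y, w):
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    syy = (w * (y - ym) ** 2).sum()
    if sxx <= 0 or syy <= 0:
        return 0.0
    sxy = (w * (x - xm) * (y - ym)).sum()
    return float(sxy**2 / (sxx * syy))


@dataclass
class CovariateBundle:
    """Model-ready design data with the scaling constants used to build it.

    ``occ_site`` columns are site-level occupancy covariates (J,); entries of
    ``occ_species_site`` are species-site matrices (S, J) such as the
    transformed distance covariate; ``det_visit`` holds visit-level detection
    covariates (J, K).  ``scaling`` records centering/scaling constants so
    prediction-time covariates can be built on the training scale.
    """

    species_ids: list
    site_ids: list
    occ_site: dict = field(default_factory=dict)
    occ_species_site: dict = field(default_factory=dict)
    det_visit: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)
    distance_scale_km: float | None = None
    signed_distance_km: np.ndarray | None = None

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def occ_column(self, name: str):
        """Return ('site', (J,)) or ('species_site', (S,J)) for a named term."""
        if name in self.occ_site:
            return "site", self.occ_site[name]
        if name in self.occ_species_site:
            return "species_site", self.occ_species_site[name]
        raise KeyError(f"no occupancy covariate named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Wide export: one row per species-site cell."""
        S, J = self.n_species, self.n_sites
        rows = {
            "species_id": np.repeat(self.species_ids, J),
            "site_id": np.tile(self.site_ids, S),
        }
        for name, col in self.occ_site.items():
            rows[name] = np.tile(col, S)
        for name, mat in self.occ_species_site.items():
            rows[name] = np.asarray(mat).ravel()
        return pd.DataFrame(rows)


def build_covariate_bundle(
    ranges: list[RangeInfo],
    sites: pd.DataFrame,
    spec,
    visit_times: np.ndarray | None = None,
    reuse_scaling: dict | None = None,
) -> CovariateBundle:
    """Assemble occupancy and detection design data for a ModelSpec.

    Site-level covariates are centered and scaled to unit SD (constants stored,
    or reused from a training bundle via ``reuse_scaling``).  Species-site
    covariates are built from range geometry / elevational limits as the ModelSpec's
    term list demands.

    Parameters
    ----------
    visit_times : optional (J, K) array for a visit-level detection covariate
        named ``time`` (e.g. hours post-sunrise).
    """
    if not ranges:
        raise ValueError("empty species list")
    sites = validate_site_table(sites)
    species_ids = [r.species_id for r in ranges]
    site_ids = sites["site_id"].tolist()
    bundle = CovariateBundle(species_ids=species_ids, site_ids=site_ids)
    scaling = dict(reuse_scaling) if reuse_scaling else {}

    occ_needed = {t.name for t in spec.occ_terms}
    det_needed = {t.name for t in spec.det_terms}

    if {"elev", "elev2"} & occ_needed:
        raw = sites["elev_m"].to_numpy(dtype=float)
        if "elev" not in scaling:
            sd = raw.std()
            scaling["elev"] = (raw.mean(), sd if sd > 0 else 1.0)
        m, s = scaling["elev"]
        std = (raw - m) / s
        if "elev" in occ_needed:
            bundle.occ_site["elev"] = std
        if "elev2" in occ_needed:
            bundle.occ_site["elev2"] = std**2

    if "distance" in occ_needed:
        missing = [r.species_id for r in ranges if not r.has_geometry]
        if missing:
            raise ValueError(f"species lacking range geometry: {missing}")
        d = signed_distance_matrix(ranges, sites)
        scale_km = getattr(spec, "distance_scale_km", 200.0)
        bundle.signed_distance_km = d
        bundle.distance_scale_km = scale_km
        bundle.occ_species_site["distance"] = scaled_inverse_logit(d, scale_km)

    if {"std_elev", "std_elev2"} & occ_needed:
        missing = [r.species_id for r in ranges if not r.has_elevation]
        if missing:
            raise ValueError(f"species lacking elevational limits: {missing}")
        lower = np.array([r.elev_lower_m for r in ranges])[:, None]
        upper = np.array([r.elev_upper_m for r in ranges])[:, None]
        s = standardize_elevation(sites["elev_m"].to_numpy(dtype=float)[None, :], lower, upper)
        if "std_elev" in occ_needed:
            bundle.occ_species_site["std_elev"] = s
        if "std_elev2" in occ_needed:
            bundle.occ_species_site["std_elev2"] = s**2

    if "habitat" in occ_needed:
        if "habitat" not in sites.columns:
            raise ValueError("site table lacks a 'habitat' column")
        bundle.occ_site["habitat"] = sites["habitat"].to_numpy(dtype=float)

    if "time" in det_needed:
        if visit_times is None:
            raise ValueError("det term 'time' requires visit_times (J, K)")
        vt = np.asarray(visit_times, dtype=float)
        if "time" not in scaling:
            sd = vt.std()
            scaling["time"] = (vt.mean(), sd if sd > 0 else 1.0)
        m, s = scaling["time"]
        bundle.det_visit["time"] = (vt - m) / s

    if "habitat" in det_needed:
        if "habitat" not in sites.columns:
            raise ValueError("site table lacks a 'habitat' column")
        bundle.det_visit["habitat"] = np.repeat(
            sites["habitat"].to_numpy(dtype=float)[:, None],
            1 if visit_times is None else np.asarray(visit_times).shape[1],
            axis=1,
        )

    known = set(bundle.occ_site) | set(bundle.occ_species_site)
    unknown = occ_needed - known
    if unknown:
        raise ValueError(f"cannot build occupancy covariates: {sorted(unknown)}")
    unknown_det = det_needed - set(bundle.det_visit)
    if unknown_det:
        raise ValueError(f"cannot build detection covariates: {sorted(unknown_det)}")

    for name, mat in bundle.occ_species_site.items():
        if not np.isfinite(mat).all():
            raise ValueError(f"non-finite covariate column {name!r}")
    bundle.scaling = scaling
    return bundle
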