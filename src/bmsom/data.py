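"""Core data containers shared by every stage of the workflow.

A multi-species occupancy dataset is a binary detection/non-detection array
``Y`` indexed by species *i*, site *j* and visit *k*, together with per-site
covariates and — for biogeographic modelling — per-species range information
(geographic polygons, elevational limits, seasonal presence windows).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

SITE_COLUMNS = ("site_id", "x_km", "y_km", "elev_m")


@dataclass
class DetectionHistory:
    """Binary detection array with a visit-level validity mask.

    Attributes
    ----------
    y : ndarray of shape (n_species, n_sites, n_visits)
        Detection (1) / non-detection (0). Entries where ``visit_mask`` is
        False are ignored by every consumer and conventionally stored as 0.
    visit_mask : bool ndarray, same shape
        True where a visit actually took place (ragged visit structures and
        temporal clipping are both expressed through this mask).
    species_ids, site_ids : lists of identifiers in array order.
    """

    y: np.ndarray
    visit_mask: np.ndarray
    species_ids: list
    site_ids: list

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.visit_mask = np.asarray(self.visit_mask, dtype=bool)
        if self.y.ndim != 3:
            raise ValueError("y must be (n_species, n_sites, n_visits)")
        if self.y.shape != self.visit_mask.shape:
            raise ValueError("y and visit_mask shapes differ")
        if len(self.species_ids) != self.y.shape[0]:
            raise ValueError("species_ids length mismatch")
        if len(self.site_ids) != self.y.shape[1]:
            raise ValueError("site_ids length mismatch")
        valid = self.y[self.visit_mask]
        if valid.size and not np.isin(valid, (0, 1)).all():
            raise ValueError("y must be binary")
        # canonical storage: masked entries are zero
        self.y = np.where(self.visit_mask, self.y, 0).astype(np.int8)

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_visits(self) -> int:
        return self.y.shape[2]

    def detected_anywhere(self) -> np.ndarray:
        """Boolean (n_species,) — species with at least one detection."""
        return self.y.any(axis=(1, 2))

    def detected_anywhere_by_cell(self) -> np.ndarray:
        """Boolean (n_species, n_sites) — any detection in the cell."""
        return self.y.any(axis=2)

    def detections_per_cell(self) -> np.ndarray:
        """Integer (n_species, n_sites) count of detections per cell."""
        return self.y.sum(axis=2)

    def to_long(self) -> pd.DataFrame:
        """Long-format (species_id, site_id, visit, y) over unmasked visits."""
        s, j, k = np.nonzero(self.visit_mask)
        return pd.DataFrame(
            {
                "species_id": [self.species_ids[i] for i in s],
                "site_id": [self.site_ids[i] for i in j],
                "visit": k + 1,
                "y": self.y[s, j, k].astype(int),
            }
        )

    def subset_species(self, index: np.ndarray) -> "DetectionHistory":
        return DetectionHistory(
            self.y[index],
            self.visit_mask[index],
            [self.species_ids[i] for i in np.atleast_1d(index)],
            list(self.site_ids),
        )


@dataclass
class RangeInfo:
    """Preexisting range knowledge for one species.

    Geometry lives in a projected, distance-preserving plane with kilometre
    units (projection choice is a data decision made upstream). Elevational
    limits are in metres; the seasonal window is a day-of-year interval and
    may wrap around the new year (``season_start > season_end``).
    """

    species_id: str
    geometry: BaseGeometry | None = None
    elev_lower_m: float | None = None
    elev_upper_m: float | None = None
    season_start: int | None = None
    season_end: int | None = None

    def __post_init__(self) -> None:
        if (self.elev_lower_m is None) != (self.elev_upper_m is None):
            raise ValueError(
                f"species {self.species_id}: elevational limits must be given "
                "as a (lower, upper) pair or not at all"
            )
        if self.elev_lower_m is not None and not (self.elev_lower_m < self.elev_upper_m):
            raise ValueError(
                f"species {self.species_id}: elev_lower_m must be < elev_upper_m"
            )
        if (self.season_start is None) != (self.season_end is None):
            raise ValueError(f"species {self.species_id}: incomplete seasonal window")
        if self.geometry is not None:
            if self.geometry.is_empty:
                raise ValueError(f"species {self.species_id}: empty range geometry")
            if not self.geometry.is_valid:
                self.geometry = make_valid(self.geometry)

    @property
    def has_geometry(self) -> bool:
        return self.geometry is not None

    @property
    def has_elevation(self) -> bool:
        return self.elev_lower_m is not None

    @property
    def is_migratory(self) -> bool:
        return self.season_start is not None


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Check the site table schema; returns the frame with site_id as str."""
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if sites["site_id"].duplicated().any():
        dup = sites.loc[sites["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids: {dup}")
    out = sites.copy()
    out["site_id"] = out["site_id"].astype(str)
    return out


@dataclass
class SimulationTruth:
    """Complete generative state of a simulated community.

    Every latent quantity needed for parameter-recovery and bias tests:
    species intercepts, slopes, occupancy/detection probabilities, the latent
    occupancy matrix Z, and the covariates as the generator computed them.
    """

    a: np.ndarray                      # (S,) occupancy intercepts
    c: np.ndarray                      # (S,) detection intercepts
    beta_elev: np.ndarray              # (S,) site-elevation slopes
    beta_dist: np.ndarray              # (S,) distance-covariate slopes (0 if unused)
    psi: np.ndarray                    # (S, J)
    theta: np.ndarray                  # (S, J, K)
    z: np.ndarray                      # (S, J) latent occupancy
    signed_distance_km: np.ndarray     # (S, J)
    distance_covariate: np.ndarray     # (S, J) scaled inverse-logit distances
    std_elevation: np.ndarray          # (S, J) species-standardized elevations
    elev_site: np.ndarray              # (J,) standardized site elevation column
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("Z must be binary")
        for name, arr in (("psi", self.psi), ("theta", self.theta)):
            if np.any(arr <= 0) or np.any(arr >= 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
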