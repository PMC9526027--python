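"""Biogeographic and temporal clipping.

Clipping removes species-site (or species-site-visit) combinations where
occupancy is a priori negligible — far beyond the mapped range, at extreme
species-standardized elevations, across an expert-drawn biogeographic barrier,
or outside a migrant's seasonal window.  Removed cells become structural
zeros: they are dropped from the likelihood entirely rather than modelled.

A detection inside a clipped cell is treated as evidence of a range-map error
of omission, not as data: :func:`validate_mask_against_detections` reports
such cells and model construction refuses to proceed while any exist.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .data import DetectionHistory, RangeInfo, validate_site_table

logger = logging.getLogger(__name__)

RETAINED = 0
REASON_BARRIER = 1
REASON_GEOGRAPHIC = 2
REASON_ELEVATION = 3
REASON_TEMPORAL = 4

#: precedence when several rules remove the same cell (lowest code wins)
REASON_NAMES = {
    RETAINED: "retained",
    REASON_BARRIER: "barrier",
    REASON_GEOGRAPHIC: "geographic_distance",
    REASON_ELEVATION: "standardized_elevation",
    REASON_TEMPORAL: "temporal",
}


@dataclass
class ClipMask:
    """Species × site retention mask with a reason code for each removed cell.

    ``visit_mask`` (optional, species × site × visit) carries visit-level
    removals from temporal clipping; a cell is removed outright only when all
    of its visits are removed.
    """

    retained: np.ndarray                      # (S, J) bool
    reason: np.ndarray                        # (S, J) int codes
    visit_mask: np.ndarray | None = None      # (S, J, K) bool
    species_ids: list | None = None
    site_ids: list | None = None

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=np.int8)
        if self.retained.shape != self.reason.shape:
            raise ValueError("retained/reason shape mismatch")
        if np.any(~self.retained & (self.reason == RETAINED)):
            raise ValueError("every removed cell needs a reason code")
        if np.any(self.retained & (self.reason != RETAINED)):
            raise ValueError("retained cells must carry no removal reason")

    @classmethod
    def full(cls, n_species: int, n_sites: int, **kw) -> "ClipMask":
        return cls(
            np.ones((n_species, n_sites), bool),
            np.zeros((n_species, n_sites), np.int8),
            **kw,
        )

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.retained).sum())

    def reason_counts(self) -> dict:
        codes, counts = np.unique(self.reason[~self.retained], return_counts=True)
        return {REASON_NAMES[int(c)]: int(n) for c, n in zip(codes, counts)}

    def to_long(self) -> pd.DataFrame:
        S, J = self.retained.shape
        sp = self.species_ids if self.species_ids is not None else list(range(S))
        st = self.site_ids if self.site_ids is not None else list(range(J))
        return pd.DataFrame(
            {
                "species_id": np.repeat(sp, J),
                "site_id": np.tile(st, S),
                "retained": self.retained.ravel(),
                "reason": [REASON_NAMES[int(r)] for r in self.reason.ravel()],
            }
        )


def clip_by_distance(distances: np.ndarray, threshold_km: float, **kw) -> ClipMask:
    """Retain cells within ``threshold_km`` of the mapped range (boundary kept)."""
    if not threshold_km > 0:
        raise ValueError("threshold_km must be > 0")
    d = np.asarray(distances, dtype=float)
    retained = d <= threshold_km
    reason = np.where(retained, RETAINED, REASON_GEOGRAPHIC).astype(np.int8)
    return ClipMask(retained, reason, **kw)


def clip_by_standardized_elevation(
    std_elev: np.ndarray,
    lower: float = -3.0,
    upper: float = 3.0,
    has_limits: np.ndarray | None = None,
    **kw,
) -> ClipMask:
    """Retain cells with species-standardized elevation in [lower, upper].

    Species without elevational limits (``has_limits`` False, or NaN rows in
    ``std_elev``) are untouched by this clip; a warning is logged.
    """
    if not lower < upper:
        raise ValueError("lower must be < upper")
    s = np.asarray(std_elev, dtype=float)
    if has_limits is None:
        has_limits = ~np.isnan(s).any(axis=1)
    has_limits = np.asarray(has_limits, dtype=bool)
    if (~has_limits).any():
        logger.warning(
            "elevational clip skipped for %d species without limits",
            int((~has_limits).sum()),
        )
    inside = np.where(
        has_limits[:, None], (s >= lower) & (s <= upper) & ~np.isnan(s), True
    )
    reason = np.where(inside, RETAINED, REASON_ELEVATION).astype(np.int8)
    return ClipMask(inside, reason, **kw)


def clip_by_barrier(
    ranges: list[RangeInfo],
    sites: pd.DataFrame,
    barriers: dict,
    **kw,
) -> ClipMask:
    """Remove cells where the site falls inside a species' exclusion polygon.

    ``barriers`` maps species_id -> shapely geometry of the excluded region
    (the far side of an expert-drawn biogeographic barrier). Species without
    an entry are untouched.
    """
    sites = validate_site_table(sites)
    pts = [Point(x, y) for x, y in zip(sites["x_km"], sites["y_km"])]
    S, J = len(ranges), len(pts)
    retained = np.ones((S, J), bool)
    for i, r in enumerate(ranges):
        geom = barriers.get(r.species_id)
        if geom is None:
            continue
        for j, p in enumerate(pts):
            if geom.covers(p):
                retained[i, j] = False
    reason = np.where(retained, RETAINED, REASON_BARRIER).astype(np.int8)
    return ClipMask(retained, reason, **kw)


def clip_temporal(
    visit_dates: np.ndarray, ranges: list[RangeInfo], **kw
) -> ClipMask:
    """Visit-level clip from seasonal presence windows (wrap-around supported).

    ``visit_dates`` is (n_sites, n_visits) day-of-year (1..366); NaN marks a
    visit that never happened.  Residents (no window) are fully retained.  A
    species-site cell is removed outright only when every visit is removed.
    """
    dates = np.asarray(visit_dates, dtype=float)
    J, K = dates.shape
    S = len(ranges)
    vmask = np.ones((S, J, K), bool)
    for i, r in enumerate(ranges):
        if not r.is_migratory:
            continue
        a, b = r.season_start, r.season_end
        if a <= b:
            ok = (dates >= a) & (dates <= b)
        else:  # wrap-around window, e.g. [300, 60]
            ok = (dates >= a) | (dates <= b)
        vmask[i] = ok | np.isnan(dates)
    retained = vmask.any(axis=2)
    reason = np.where(retained, RETAINED, REASON_TEMPORAL).astype(np.int8)
    return ClipMask(retained, reason, visit_mask=vmask, **kw)


def combine_masks(masks: list[ClipMask]) -> ClipMask:
    """Logical AND of masks; reasons follow the documented precedence order
    (barrier > geographic_distance > standardized_elevation > temporal)."""
    if not masks:
        raise ValueError("no masks to combine")
    shape = masks[0].retained.shape
    for m in masks[1:]:
        if m.retained.shape != shape:
            raise ValueError("mask dimension mismatch")
    retained = np.ones(shape, bool)
    reason = np.full(shape, 127, np.int8)
    vmask = None
    for m in masks:
        retained &= m.retained
        removed = ~m.retained
        reason[removed] = np.minimum(reason[removed], m.reason[removed])
        if m.visit_mask is not None:
            vmask = m.visit_mask if vmask is None else (vmask & m.visit_mask)
    reason[retained] = RETAINED
    reason[~retained & (reason == 127)] = RETAINED  # unreachable guard
    sp = next((m.species_ids for m in masks if m.species_ids is not None), None)
    st = next((m.site_ids for m in masks if m.site_ids is not None), None)
    return ClipMask(retained, reason, visit_mask=vmask, species_ids=sp, site_ids=st)


def validate_mask_against_detections(
    mask: ClipMask, history: DetectionHistory
) -> list[tuple]:
    """Cells removed by the mask that nonetheless contain a detection.

    A non-empty return signals errors of omission in the range information;
    model fitting refuses to proceed until the ranges (or mask) are fixed.
    Returns (species_id, site_id) pairs.
    """
    if mask.retained.shape != (history.n_species, history.n_sites):
        raise ValueError("mask dimensions do not match detection history")
    det = history.detected_anywhere_by_cell()
    bad_cell = det & ~mask.retained
    out = [
        (history.species_ids[i], history.site_ids[j])
        for i, j in zip(*np.nonzero(bad_cell))
    ]
    if mask.visit_mask is not None:
        # visit-level: detections at temporally removed visits of retained cells
        bad_visit = (history.y.astype(bool) & ~mask.visit_mask) & mask.retained[
            :, :, None
        ]
        for i, j in zip(*np.nonzero(bad_visit.any(axis=2))):
            out.append((history.species_ids[i], history.site_ids[j]))
    return sorted(set(out), key=lambda t: (str(t[0]), str(t[1])))


def max_detection_distance(
    history: DetectionHistory, distances: np.ndarray
) -> float:
    """Largest distance-to-range at which any detection occurred.

    An exploratory report to inform the user's choice of clipping threshold;
    the package deliberately performs no automatic threshold selection.
    """
    det = history.detected_anywhere_by_cell()
    if not det.any():
        return float("nan")
    return float(np.asarray(distances)[det].max())
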