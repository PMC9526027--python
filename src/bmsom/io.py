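"""Readers and writers for the interchange formats.

Long-format CSV is the canonical detection interchange (species_id, site_id,
visit, y); range polygons travel as GeoJSON in a projected kilometre-unit
plane (a named CRS is required — geographic coordinates are refused);
elevational limits and seasonal windows are per-species CSVs.  Dates are
ISO-8601 in files and day-of-year internally.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .data import DetectionHistory, RangeInfo, validate_site_table

logger = logging.getLogger(__name__)

#: CRS names treated as geographic (degree units) and therefore refused
_GEOGRAPHIC_CRS = {
    "urn:ogc:def:crs:OGC:1.3:CRS84",
    "urn:ogc:def:crs:OGC::CRS84",
    "EPSG:4326",
    "urn:ogc:def:crs:EPSG::4326",
}

#: CRS name written by this package for its synthetic local kilometre plane
LOCAL_KM_CRS = "urn:bmsom:local-plane-km"


# -- detection histories -----------------------------------------------------------


def read_detection_csv(path) -> DetectionHistory:
    """Long CSV -> dense array with a visit mask for ragged visit structures.

    Species and sites are ordered lexicographically; a (species, site, visit)
    triple absent from the file is masked, not zero-filled.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "site_id": str})
    required = {"species_id", "site_id", "visit", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    dup = df.duplicated(["species_id", "site_id", "visit"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"duplicate (species, site, visit) rows at lines {rows}")
    if not df["y"].isin([0, 1]).all():
        rows = (df.index[~df["y"].isin([0, 1])] + 2).tolist()
        raise ValueError(f"y outside {{0,1}} at lines {rows}")
    species = sorted(df["species_id"].unique())
    sites = sorted(df["site_id"].unique())
    visits = sorted(df["visit"].unique())
    k_index = {v: i for i, v in enumerate(visits)}
    s_index = {s: i for i, s in enumerate(species)}
    j_index = {s: i for i, s in enumerate(sites)}
    S, J, K = len(species), len(sites), len(visits)
    y = np.zeros((S, J, K), np.int8)
    mask = np.zeros((S, J, K), bool)
    si = df["species_id"].map(s_index).to_numpy()
    ji = df["site_id"].map(j_index).to_numpy()
    ki = df["visit"].map(k_index).to_numpy()
    y[si, ji, ki] = df["y"].to_numpy()
    mask[si, ji, ki] = True
    return DetectionHistory(y, mask, species, sites)


def write_detection_csv(history: DetectionHistory, path) -> None:
    history.to_long().to_csv(path, index=False)


# -- range information ------------------------------------------------------------


def write_ranges_geojson(ranges: list, path, crs_name: str = LOCAL_KM_CRS) -> None:
    features = []
    for r in ranges:
        if not r.has_geometry:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": {"species_id": r.species_id},
                "geometry": mapping(r.geometry),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_name}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def write_elev_limits_csv(ranges: list, path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "elev_lower_m": r.elev_lower_m,
            "elev_upper_m": r.elev_upper_m,
        }
        for r in ranges
        if r.has_elevation
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_seasons_csv(ranges: list, path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "start_doy": r.season_start,
            "end_doy": r.season_end,
        }
        for r in ranges
        if r.is_migratory
    ]
    pd.DataFrame(rows, columns=["species_id", "start_doy", "end_doy"]).to_csv(
        path, index=False
    )


def read_ranges(
    geojson_path,
    limits_csv=None,
    seasons_csv=None,
    species_ids: list | None = None,
    strict: bool = True,
) -> list:
    """Merge polygons, elevational limits and seasonal windows per species.

    The GeoJSON must declare a named, projected (kilometre-unit) CRS;
    geographic coordinates are refused with an instruction to reproject.
    ``species_ids``, when given, fixes the output ordering and triggers a
    warning list for unmatched species.
    """
    doc = json.loads(Path(geojson_path).read_text())
    crs = doc.get("crs")
    name = crs.get("properties", {}).get("name") if isinstance(crs, dict) else None
    if name is None or name in _GEOGRAPHIC_CRS:
        raise ValueError(
            "range GeoJSON must declare a named projected CRS in kilometre "
            "units; reproject geographic (lon/lat) polygons before import"
        )
    geoms: dict[str, object] = {}
    for f in doc.get("features", []):
        sid = str(f.get("properties", {}).get("species_id"))
        geom = shape(f["geometry"])
        if not geom.is_valid:
            if strict:
                raise ValueError(f"invalid polygon for species {sid}")
            from shapely.validation import make_valid

            geom = make_valid(geom)
        geoms[sid] = geoms[sid].union(geom) if sid in geoms else geom

    limits: dict[str, tuple] = {}
    if limits_csv is not None:
        lf = pd.read_csv(limits_csv, dtype={"species_id": str})
        for _, row in lf.iterrows():
            limits[row["species_id"]] = (
                float(row["elev_lower_m"]),
                float(row["elev_upper_m"]),
            )
    seasons: dict[str, tuple] = {}
    if seasons_csv is not None:
        sf = pd.read_csv(seasons_csv, dtype={"species_id": str})
        for _, row in sf.iterrows():
            if pd.notna(row["start_doy"]):
                seasons[row["species_id"]] = (
                    int(row["start_doy"]),
                    int(row["end_doy"]),
                )

    all_ids = species_ids or sorted(set(geoms) | set(limits) | set(seasons))
    unmatched = [s for s in all_ids if s not in geoms and s not in limits]
    if unmatched:
        logger.warning("species with no range information: %s", unmatched)
    out = []
    for sid in all_ids:
        lo, hi = limits.get(sid, (None, None))
        st, en = seasons.get(sid, (None, None))
        out.append(
            RangeInfo(
                species_id=sid,
                geometry=geoms.get(sid),
                elev_lower_m=lo,
                elev_upper_m=hi,
                season_start=st,
                season_end=en,
            )
        )
    return out


# -- site tables, masks, draws -----------------------------------------------------


def read_site_csv(path) -> pd.DataFrame:
    return validate_site_table(pd.read_csv(path, dtype={"site_id": str}))


def write_site_csv(sites: pd.DataFrame, path) -> None:
    validate_site_table(sites).to_csv(path, index=False)


def write_clip_mask_csv(mask, path) -> None:
    mask.to_long().to_csv(path, index=False)


def read_clip_mask_csv(path, species_ids: list, site_ids: list):
    from .clipping import ClipMask, REASON_NAMES

    code = {v: k for k, v in REASON_NAMES.items()}
    df = pd.read_csv(path, dtype={"species_id": str, "site_id": str})
    S, J = len(species_ids), len(site_ids)
    s_index = {s: i for i, s in enumerate(species_ids)}
    j_index = {s: i for i, s in enumerate(site_ids)}
    retained = np.ones((S, J), bool)
    reason = np.zeros((S, J), np.int8)
    for _, row in df.iterrows():
        i, j = s_index[row["species_id"]], j_index[row["site_id"]]
        retained[i, j] = bool(row["retained"])
        reason[i, j] = code[row["reason"]]
    return ClipMask(retained, reason, species_ids=species_ids, site_ids=site_ids)


def write_draws_csv(results, path) -> None:
    results.to_frame().to_csv(path, index=False)


def dates_to_doy(dates) -> np.ndarray:
    """ISO-8601 date strings -> day-of-year integers."""
    return pd.to_datetime(pd.Series(dates)).dt.dayofyear.to_numpy()


def read_draws_csv(model, path):
    """Rebuild an OccupancyResults from a draws CSV written by write_draws_csv.

    Sampler metadata (energies, divergences) is not persisted, so the
    reconstructed results support posterior summaries and predictive
    quantities but not the energy-based diagnostics.
    """
    from .results import OccupancyResults
    from .sampler import ChainStats

    df = pd.read_csv(path)
    chains = int(df["chain"].max()) + 1
    ndraws = int(df["draw"].max()) + 1
    lay = model.layout
    draws = np.empty((chains, ndraws, lay.dim))
    for name, sl in lay.slices.items():
        width = sl.stop - sl.start
        if width == 1:
            draws[:, :, sl.start] = df[name].to_numpy().reshape(chains, ndraws)
        else:
            for k in range(width):
                draws[:, :, sl.start + k] = (
                    df[f"{name}[{k}]"].to_numpy().reshape(chains, ndraws)
                )
    stats = [
        ChainStats(
            energy=np.full(ndraws, np.nan), divergent=np.zeros(ndraws, bool),
            accept_stat=np.full(ndraws, np.nan), treedepth=np.zeros(ndraws, int),
            step_size=np.nan, inv_mass=np.ones(lay.dim),
        )
        for _ in range(chains)
    ]
    return OccupancyResults(model, draws, stats)
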