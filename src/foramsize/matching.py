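"""Attach environmental and abundance covariates to morphometric sites.

SST and NPP come from long-format gridded climatology tables via the
geodesically nearest grid node.  Species relative abundances come from
an assemblage compilation two ways: the single nearest record, and the
per-species median over all records within a drift radius (300 km by
default, the maximum postmortem transport of settling shells).  All
distances are WGS-84 ellipsoidal geodesics; every match reports its
distance for quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesy import geodesic_km_many, haversine_km_many

__all__ = ["CovariateGrid", "nearest_match", "radius_median_abundance", "match_sites"]

# haversine-to-geodesic ratio never strays more than ~0.6% from 1, so a
# 2% margin around the minimum haversine distance is a safe candidate set
_PREFILTER_MARGIN = 1.02
# distances agreeing to a nanometre are treated as exact ties
_TIE_KM = 1e-12


@dataclass
class CovariateGrid:
    """Long-format covariate table: one row per (latitude, longitude)."""

    table: pd.DataFrame
    name: str = "value"
    units: str = ""

    def __post_init__(self):
        t = self.table
        for col in ("latitude", "longitude", "value"):
            if col not in t.columns:
                raise ValueError(f"grid table missing column {col!r}")
        if len(t) == 0:
            raise ValueError("empty covariate grid")
        if not np.isfinite(t[["latitude", "longitude", "value"]].to_numpy()).all():
            raise ValueError("non-finite entries in covariate grid")
        if t.duplicated(subset=["latitude", "longitude"]).any():
            raise ValueError("duplicate coordinates in covariate grid")


def _nearest_index(lat: float, lon: float, lats: np.ndarray, lons: np.ndarray):
    """Index of the geodesically nearest record, with a haversine
    prefilter and a deterministic tie-break (lowest latitude, then
    lowest longitude)."""
    dh = haversine_km_many(lat, lon, lats, lons)
    cut = dh.min() * _PREFILTER_MARGIN + 1e-9
    cand = np.flatnonzero(dh <= cut)
    dg = geodesic_km_many(lat, lon, lats[cand], lons[cand])
    dmin = dg.min()
    ties = cand[np.flatnonzero(dg <= dmin + _TIE_KM)]
    order = np.lexsort((lons[ties], lats[ties]))
    best = int(ties[order[0]])
    return best, float(dg[np.searchsorted(cand, best)])


def nearest_match(lat: float, lon: float, grid: CovariateGrid):
    """Grid value at the geodesically nearest node.

    Returns ``(value, distance_km)``.  Exact distance ties are broken
    deterministically by lowest latitude, then lowest longitude.
    """
    t = grid.table
    i, d = _nearest_index(lat, lon, t["latitude"].to_numpy(float), t["longitude"].to_numpy(float))
    return float(t["value"].iloc[i]), d


def radius_median_abundance(
    lat: float,
    lon: float,
    assemblage: pd.DataFrame,
    radius_km: float = 300.0,
):
    """Per-species median relative abundance over in-radius records.

    Records are assemblage samples (unique coordinates, possibly shared
    by several species rows).  The radius boundary is closed
    (distance <= radius).  If no record falls inside the radius the
    single nearest record is used instead, with a warning, so the site
    remains analyzable.

    Returns a DataFrame (species, abundance, n_records, used_fallback)
    plus the nearest-record distance in a second return value.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    if len(assemblage) == 0:
        raise ValueError("empty assemblage table")
    for col in ("latitude", "longitude", "species", "abundance"):
        if col not in assemblage.columns:
            raise ValueError(f"assemblage table missing column {col!r}")

    coords = assemblage[["latitude", "longitude"]].drop_duplicates().reset_index(drop=True)
    d = geodesic_km_many(lat, lon, coords["latitude"].to_numpy(float),
                         coords["longitude"].to_numpy(float))
    coords = coords.assign(_dist_km=d)
    nearest_km = float(d.min())
    inside = coords[coords["_dist_km"] <= radius_km]
    used_fallback = False
    if len(inside) == 0:
        used_fallback = True
        warnings.warn(
            f"no assemblage record within {radius_km} km of ({lat}, {lon}); "
            "falling back to the nearest record",
            stacklevel=2,
        )
        ties = coords[coords["_dist_km"] <= nearest_km + _TIE_KM]
        order = np.lexsort((ties["longitude"].to_numpy(), ties["latitude"].to_numpy()))
        inside = ties.iloc[[order[0]]]
    sel = assemblage.merge(inside[["latitude", "longitude"]], on=["latitude", "longitude"])
    out = (
        sel.groupby("species", sort=True)["abundance"]
        .median()
        .reset_index()
    )
    out["n_records"] = len(inside)
    out["used_fallback"] = used_fallback
    return out, nearest_km


def _nearest_abundance(lat, lon, assemblage):
    coords = assemblage[["latitude", "longitude"]].drop_duplicates().reset_index(drop=True)
    i, d = _nearest_index(lat, lon, coords["latitude"].to_numpy(float),
                          coords["longitude"].to_numpy(float))
    row = coords.iloc[i]
    sel = assemblage[(assemblage["latitude"] == row["latitude"])
                     & (assemblage["longitude"] == row["longitude"])]
    return sel[["species", "abundance"]].reset_index(drop=True), d


def match_sites(
    sites: pd.DataFrame,
    sst_grid: CovariateGrid | pd.DataFrame,
    npp_grid: CovariateGrid | pd.DataFrame,
    assemblage: pd.DataFrame,
    radius_km: float = 300.0,
):
    """Match every site to SST, NPP and abundance covariates.

    Returns ``(site_covariates, abundance_long)``:

    * ``site_covariates``: site_id, sst, sst_km, npp, npp_km,
      abund_nearest_km, abund_n_records
    * ``abundance_long``: site_id, species, abund_nearest,
      abund_radius_median
    """
    if isinstance(sst_grid, pd.DataFrame):
        sst_grid = CovariateGrid(sst_grid, "sst", "degC")
    if isinstance(npp_grid, pd.DataFrame):
        npp_grid = CovariateGrid(npp_grid, "npp", "mg C m-2 day-1")
    site_rows = []
    ab_rows = []
    for _, s in sites.iterrows():
        lat, lon = float(s["latitude"]), float(s["longitude"])
        sst, dsst = nearest_match(lat, lon, sst_grid)
        npp, dnpp = nearest_match(lat, lon, npp_grid)
        near_ab, dab = _nearest_abundance(lat, lon, assemblage)
        med_ab, _ = radius_median_abundance(lat, lon, assemblage, radius_km=radius_km)
        merged = near_ab.rename(columns={"abundance": "abund_nearest"}).merge(
            med_ab.rename(columns={"abundance": "abund_radius_median"}),
            on="species", how="outer",
        )
        merged.insert(0, "site_id", s["site_id"])
        ab_rows.append(merged)
        site_rows.append({
            "site_id": s["site_id"], "sst": sst, "sst_km": dsst,
            "npp": npp, "npp_km": dnpp,
            "abund_nearest_km": dab,
            "abund_n_records": int(merged["n_records"].iloc[0]),
        })
    site_cov = pd.DataFrame(site_rows)
    abundance = pd.concat(ab_rows, ignore_index=True)[
        ["site_id", "species", "abund_nearest", "abund_radius_median", "used_fallback"]
    ]
    return site_cov, abundance
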