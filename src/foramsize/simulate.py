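"""Seeded synthetic datasets with the structure the analysis assumes.

Every downstream stage (population summaries, collector-bias audit,
covariate matching, model selection) can run on these tables with no
external data.  The root seed is split into per-stage child streams
(numpy ``SeedSequence``/PCG64), so each stage is independently
reproducible and byte-identical under a fixed seed.

Generated tables
----------------
sites        : site_id, latitude, longitude, sst, npp (latent truth)
grids        : 1-degree long-format covariate tables (latitude,
               longitude, value) for SST and NPP
assemblage   : sample_id, latitude, longitude, species, abundance
specimens    : specimen_id, species, site_id, latitude, longitude,
               area (um^2), collection
truth        : species, site_id, target_logp95 (the population's exact
               log 95th percentile before any finite-sample noise)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, Z95
from .geodesy import normalize_lon

__all__ = [
    "SyntheticDataset",
    "simulate_environment",
    "simulate_abundances",
    "simulate_specimens",
    "apply_collector_bias",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

BASELINE_COLLECTION = "bulk"     # unbiased resampled bulk sediment
BIASED_COLLECTION = "museum"     # size-selective hand-picked collection

_KM_PER_DEG_LAT = 111.32


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["environment", "grids", "abundance", "specimens", "pool", "bias", "assemblage"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _sst_profile(lat, config: SimulationConfig):
    lat_max = max(abs(config.lat_range[0]), abs(config.lat_range[1]))
    drop = config.sst_mean_equator - config.sst_mean_edge
    return config.sst_mean_equator - drop * (np.abs(lat) / lat_max) ** 2


def _npp_from_sst(sst, rho, config, rng):
    z = (sst - sst.mean()) / sst.std(ddof=0)
    eps = rng.standard_normal(len(sst))
    npp = config.npp_mean + config.npp_sd * (rho * z + math.sqrt(1.0 - rho ** 2) * eps)
    return np.maximum(npp, 5.0)


def simulate_environment(config: SimulationConfig, rng=None, grid_rng=None):
    """Draw site coordinates and latent SST/NPP, plus covariate grids.

    Site SST follows a smooth quadratic decline in |latitude| plus
    Gaussian noise; NPP is built from standardized SST plus independent
    noise so the realized Pearson correlation converges to
    ``target_sst_npp_corr``.  Grid nodes (1-degree spacing over the
    site latitude band, all longitudes) carry the same construction
    evaluated independently, so matched covariates behave like noisy
    measurements of the site truth.

    Returns ``(sites, grids)`` where ``grids`` maps ``"sst"``/``"npp"``
    to long-format (latitude, longitude, value) tables.
    """
    if rng is None or grid_rng is None:
        s = _streams(config.seed)
        rng = rng or s["environment"]
        grid_rng = grid_rng or s["grids"]
    lo, hi = config.lat_range
    if hi - lo <= 0:
        raise ValueError("degenerate lat_range")
    n = config.n_sites
    lat = rng.uniform(lo, hi, n)
    lon = normalize_lon(rng.uniform(-180.0, 180.0, n))
    sst = _sst_profile(lat, config) + rng.normal(0.0, config.sst_noise_sd, n)
    npp = _npp_from_sst(sst, config.target_sst_npp_corr, config, rng)
    sites = pd.DataFrame({
        "site_id": [f"site_{i:03d}" for i in range(n)],
        "latitude": lat,
        "longitude": lon,
        "sst": sst,
        "npp": npp,
    })

    glat = np.arange(math.floor(lo) - 2.0, math.ceil(hi) + 2.0 + 0.5, 1.0)
    glon = np.arange(-180.0, 180.0, 1.0)
    gg_lat, gg_lon = np.meshgrid(glat, glon, indexing="ij")
    gg_lat, gg_lon = gg_lat.ravel(), gg_lon.ravel()
    gsst = _sst_profile(gg_lat, config) + grid_rng.normal(0.0, config.sst_noise_sd, gg_lat.size)
    gnpp = _npp_from_sst(gsst, config.target_sst_npp_corr, config, grid_rng)
    grids = {
        "sst": pd.DataFrame({"latitude": gg_lat, "longitude": gg_lon, "value": gsst}),
        "npp": pd.DataFrame({"latitude": gg_lat, "longitude": gg_lon, "value": gnpp}),
    }
    return sites, grids


def gaussian_niche_abundance(sst, centers, widths):
    """Relative abundances from Gaussian thermal niches.

    Species weight at a site is exp(-(SST - T_opt)^2 / (2 sigma^2));
    relative abundance is the weight normalized across species.
    """
    sst = np.asarray(sst, dtype=float)
    w = np.exp(-((sst[:, None] - np.asarray(centers)[None, :]) ** 2)
               / (2.0 * np.asarray(widths)[None, :] ** 2))
    tot = w.sum(axis=1)
    if np.any(tot <= 0.0) or not np.all(np.isfinite(tot)):
        bad = np.flatnonzero(~(tot > 0.0))
        raise FloatingPointError(
            f"all species weights vanished at {bad.size} site(s) "
            f"(first index {bad[0]}): niches too narrow for the local SST"
        )
    return w / tot[:, None]


def simulate_abundances(sites: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Long-format species relative abundances at each site."""
    ab = gaussian_niche_abundance(
        sites["sst"].to_numpy(), config.sst_niche_centers, config.sst_niche_widths
    )
    out = pd.DataFrame({
        "site_id": np.repeat(sites["site_id"].to_numpy(), config.n_species),
        "species": np.tile(np.asarray(config.species_names), len(sites)),
        "abundance": ab.ravel(),
    })
    return out


def simulate_assemblage(sites: pd.DataFrame, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """ForCenS-like assemblage records: one record at each site plus
    ``records_per_site - 1`` records jittered within ``drift_km``."""
    if rng is None:
        rng = _streams(config.seed)["assemblage"]
    recs = []
    k = 0
    for _, row in sites.iterrows():
        for j in range(config.records_per_site):
            if j == 0:
                rlat, rlon = row["latitude"], row["longitude"]
            else:
                r = config.drift_km * math.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                rlat = row["latitude"] + (r * math.cos(theta)) / _KM_PER_DEG_LAT
                rlat = float(np.clip(rlat, -89.9, 89.9))
                rlon = row["longitude"] + (r * math.sin(theta)) / (
                    _KM_PER_DEG_LAT * max(math.cos(math.radians(rlat)), 0.05)
                )
                rlon = float(normalize_lon(rlon))
            sst = _sst_profile(np.array([rlat]), config)[0] + rng.normal(0.0, config.sst_noise_sd)
            ab = gaussian_niche_abundance(
                np.array([sst]), config.sst_niche_centers, config.sst_niche_widths
            )[0]
            for sp, a in zip(config.species_names, ab):
                recs.append((f"rec_{k:04d}", rlat, rlon, sp, a))
            k += 1
    return pd.DataFrame(recs, columns=["sample_id", "latitude", "longitude", "species", "abundance"])


def simulate_specimens(
    sites: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
    truth: pd.DataFrame | None = None,
    individuals_per_site: int | None = None,
    collection: str = BASELINE_COLLECTION,
    id_prefix: str = "spec",
):
    """Individual shell areas for every species x site population.

    The population's target log 95th percentile is
    ``b0 + b1*SST + b2*SST^2 + b3*NPP + eps`` with site noise
    ``eps ~ N(0, site_noise_sd)``; individual log areas are
    ``N(target - Z95*individual_log_sd, individual_log_sd)`` so the
    theoretical population 95th percentile equals the target.

    Passing an existing ``truth`` table reuses its per-population
    targets, yielding an independent collection drawn from the same
    populations (e.g. the pool a collector later screens).

    Returns ``(specimens, truth)``.
    """
    n_ind = int(individuals_per_site if individuals_per_site is not None
                else config.individuals_per_site)
    if n_ind < 1:
        raise ValueError("individuals_per_site must be >= 1")
    if rng is None:
        rng = _streams(config.seed)["specimens"]
    n_sites = len(sites)
    n_sp = config.n_species
    sst = sites["sst"].to_numpy(float)
    npp = sites["npp"].to_numpy(float)
    if truth is None:
        b = config.size_coefficients  # (n_sp, 4)
        base = (b[:, 0][:, None] + b[:, 1][:, None] * sst[None, :]
                + b[:, 2][:, None] * sst[None, :] ** 2 + b[:, 3][:, None] * npp[None, :])
        targets = base + rng.normal(0.0, config.site_noise_sd, (n_sp, n_sites))
    else:
        t = truth.set_index(["species", "site_id"])["target_logp95"]
        targets = np.array([
            [t.loc[(sp, site)] for site in sites["site_id"]]
            for sp in config.species_names
        ])
    logs = rng.normal(targets[:, :, None] - Z95 * config.individual_log_sd,
                      config.individual_log_sd, (n_sp, n_sites, n_ind))
    # row order: species-major within site? keep (site, species, individual)
    logs = np.transpose(logs, (1, 0, 2))  # (site, species, individual)
    total = n_sites * n_sp * n_ind
    specimens = pd.DataFrame({
        "specimen_id": [f"{id_prefix}_{i:06d}" for i in range(total)],
        "species": np.tile(np.repeat(np.asarray(config.species_names), n_ind), n_sites),
        "site_id": np.repeat(sites["site_id"].to_numpy(), n_sp * n_ind),
        "latitude": np.repeat(sites["latitude"].to_numpy(), n_sp * n_ind),
        "longitude": np.repeat(sites["longitude"].to_numpy(), n_sp * n_ind),
        "area": np.exp(logs.ravel()),
        "collection": collection,
    })
    truth_out = pd.DataFrame({
        "species": np.tile(np.asarray(config.species_names), n_sites),
        "site_id": np.repeat(sites["site_id"].to_numpy(), n_sp),
        "target_logp95": np.transpose(targets).ravel(),
    })
    return specimens, truth_out


def apply_collector_bias(specimens: pd.DataFrame, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Size-selective retention emulating a hand-picked museum collection.

    Each specimen is retained independently with probability
    ``logistic((log area - bias_midpoint) / bias_steepness)``.  The
    retained set is returned with its ``collection`` label switched to
    the biased collection as provenance.
    """
    if rng is None:
        rng = _streams(config.seed)["bias"]
    logs = np.log(specimens["area"].to_numpy())
    z = (logs - config.bias_midpoint) / config.bias_steepness
    p = 1.0 / (1.0 + np.exp(-z))
    keep = rng.uniform(size=len(specimens)) < p
    out = specimens.loc[keep].copy()
    out["collection"] = BIASED_COLLECTION
    if len(out) == 0:
        logger.warning("collector bias retained no specimens")
    return out.reset_index(drop=True)


@dataclass
class SyntheticDataset:
    """Bundle of all generated tables plus the generating truth."""

    config: SimulationConfig
    sites: pd.DataFrame
    grids: dict[str, pd.DataFrame]
    assemblage: pd.DataFrame
    specimens: pd.DataFrame          # unbiased baseline collection
    specimens_biased: pd.DataFrame   # after collector retention
    truth: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "sites.csv": self.sites,
            "grid_sst.csv": self.grids["sst"],
            "grid_npp.csv": self.grids["npp"],
            "assemblage.csv": self.assemblage,
            "specimens_bulk.csv": self.specimens,
            "specimens_museum.csv": self.specimens_biased,
            "truth.csv": self.truth,
        }
        for name, df in tables.items():
            p = outdir / name
            df.to_csv(p, index=False)
            paths[name] = str(p)
        self.config.to_yaml(outdir / "sim_config.yaml")
        paths["sim_config.yaml"] = str(outdir / "sim_config.yaml")
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage under per-stage child streams."""
    streams = _streams(config.seed)
    sites, grids = simulate_environment(config, rng=streams["environment"], grid_rng=streams["grids"])
    assemblage = simulate_assemblage(sites, config, rng=streams["assemblage"])
    specimens, truth = simulate_specimens(sites, config, rng=streams["specimens"])
    # the collector screens a larger, independent pool from the same
    # populations and keeps a size-biased subset
    n_pool = max(1, round(config.collector_pool_factor * config.individuals_per_site))
    pool, _ = simulate_specimens(
        sites, config, rng=streams["pool"], truth=truth,
        individuals_per_site=n_pool, id_prefix="pool",
    )
    biased = apply_collector_bias(pool, config, rng=streams["bias"])
    return SyntheticDataset(
        config=config, sites=sites, grids=grids, assemblage=assemblage,
        specimens=specimens, specimens_biased=biased, truth=truth,
    )
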