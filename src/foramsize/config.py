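"""Simulation configuration.

The synthetic generator emulates the statistical structure the analysis
assumes: tropical/subtropical sites, a zonal SST field, NPP correlated
with SST, Gaussian thermal niches turning SST into species relative
abundances, lognormal individual shell areas whose population 95th
percentile responds to SST and NPP, and a size-selective (logistic)
collector retention process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["SimulationConfig", "Z95"]

#: 95th percentile of the standard normal; with individual log areas
#: N(target - Z95*sigma_ind, sigma_ind) the population's theoretical
#: 95th percentile equals the target exactly.
Z95 = 1.6449


def _per_species(value, n_species, name):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_species, float(arr))
    if arr.shape != (n_species,):
        raise ValueError(f"{name} must be scalar or length n_species={n_species}, got shape {arr.shape}")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults describe the study conditions emulated throughout the
    test-suite: nine species over ~50 tropical/subtropical sites within
    +-40 deg latitude, SST-NPP correlation 0.4, a dozen measured
    individuals per population, and a collector retention logistic
    centred near the population mean log area.

    Parameters
    ----------
    n_species, n_sites : int
        Numbers of species and of seafloor sediment sites.
    lat_range : (float, float)
        Latitude band sampled uniformly, degrees.
    sst_niche_centers, sst_niche_widths : per-species arrays, deg C
        Thermal optimum T_opt and niche breadth sigma of the Gaussian
        abundance response of each species.
    size_coefficients : (n_species, 4) array
        Rows (b0, b1, b2, b3): intercept, SST slope, SST^2 term and NPP
        slope of each species' population log-95th-percentile
        (natural-log um^2 scale).
    site_noise_sd : float
        SD of the site-level deviation of the true log P95, log-units.
    individual_log_sd : float
        SD of individual log areas around the population location.
    individuals_per_site : int
        Specimens measured per species x site population.
    sst_mean_equator, sst_mean_edge : float
        Zonal SST profile values at the equator and at the edge of
        ``lat_range`` (quadratic decline in |latitude|), deg C.
    sst_noise_sd : float
        SD of site/grid-node SST deviations from the zonal profile.
    npp_mean, npp_sd : float
        Marginal mean and SD of NPP, mg C m^-2 day^-1.
    target_sst_npp_corr : float
        Pearson correlation between site SST and NPP the generator
        reproduces (NPP = correlated share of standardized SST plus
        independent noise).
    bias_midpoint, bias_steepness : float
        Collector retention probability is
        logistic((log area - midpoint)/steepness); log-units.
    collector_pool_factor : float
        The collector screens ``collector_pool_factor`` times as many
        individuals per population as the baseline sample and keeps a
        size-biased subset, emulating a hand-picked museum collection
        drawn from bulk sediment.
    records_per_site, drift_km : int, float
        Assemblage records emulating a ForCenS-like compilation: one
        record at each site plus ``records_per_site - 1`` records
        jittered within ``drift_km`` (postmortem drift radius).
    seed : int
        Root seed; every stage draws from an independent child stream.
    """

    n_species: int = 9
    n_sites: int = 50
    lat_range: tuple[float, float] = (-40.0, 40.0)
    sst_niche_centers: Sequence[float] | float | None = None
    sst_niche_widths: Sequence[float] | float = 4.0
    size_coefficients: Sequence[Sequence[float]] | None = None
    site_noise_sd: float = 0.1
    individual_log_sd: float = 0.5
    individuals_per_site: int = 12
    sst_mean_equator: float = 29.0
    sst_mean_edge: float = 15.0
    sst_noise_sd: float = 1.0
    npp_mean: float = 520.0
    npp_sd: float = 140.0
    target_sst_npp_corr: float = 0.4
    bias_midpoint: float = 10.5
    bias_steepness: float = 0.4
    collector_pool_factor: float = 4.0
    records_per_site: int = 3
    drift_km: float = 150.0
    seed: int = 0
    species_names: Sequence[str] = field(default=())

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        lo, hi = self.lat_range
        if not (-90.0 <= lo < hi <= 90.0):
            raise ValueError(f"lat_range must be increasing and within +-90, got {self.lat_range}")
        for name in ("site_noise_sd", "individual_log_sd", "sst_noise_sd", "npp_sd", "bias_steepness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.individuals_per_site < 1:
            raise ValueError("individuals_per_site must be >= 1")
        if not -1.0 <= self.target_sst_npp_corr <= 1.0:
            raise ValueError("target_sst_npp_corr must be in [-1, 1]")
        if self.records_per_site < 1:
            raise ValueError("records_per_site must be >= 1")
        if self.collector_pool_factor < 1:
            raise ValueError("collector_pool_factor must be >= 1")

        if self.sst_niche_centers is None:
            self.sst_niche_centers = np.linspace(16.0, 29.0, self.n_species)
        self.sst_niche_centers = _per_species(self.sst_niche_centers, self.n_species, "sst_niche_centers")
        self.sst_niche_widths = _per_species(self.sst_niche_widths, self.n_species, "sst_niche_widths")
        if np.any(self.sst_niche_widths <= 0):
            raise ValueError("sst_niche_widths must be > 0")

        if self.size_coefficients is None:
            # pure linear SST effect by default
            self.size_coefficients = np.tile([10.0, 0.05, 0.0, 0.0], (self.n_species, 1))
        self.size_coefficients = np.asarray(self.size_coefficients, dtype=float)
        if self.size_coefficients.shape != (self.n_species, 4):
            raise ValueError(
                f"size_coefficients must have shape (n_species, 4), got {self.size_coefficients.shape}"
            )

        if not self.species_names:
            self.species_names = tuple(f"species_{i:02d}" for i in range(self.n_species))
        self.species_names = tuple(str(s) for s in self.species_names)
        if len(self.species_names) != self.n_species:
            raise ValueError("species_names length must equal n_species")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sst_niche_centers"] = [float(x) for x in self.sst_niche_centers]
        d["sst_niche_widths"] = [float(x) for x in self.sst_niche_widths]
        d["size_coefficients"] = [[float(x) for x in row] for row in self.size_coefficients]
        d["lat_range"] = [float(self.lat_range[0]), float(self.lat_range[1])]
        d["species_names"] = list(self.species_names)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["lat_range"] = tuple(d["lat_range"])
        return cls(**d)
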