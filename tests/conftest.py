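import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import foramsize as fs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by read-only tests."""
    cfg = fs.SimulationConfig(n_species=4, n_sites=12, individuals_per_site=10, seed=123)
    return fs.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def truth_populations(small_dataset):
    """Populations table built from the generating truth (exact log P95)."""
    ds = small_dataset
    ab = fs.simulate_abundances(ds.sites, ds.config)
    pops = ds.truth.merge(ds.sites, on="site_id").merge(ab, on=["site_id", "species"])
    pops = pops.rename(columns={"target_logp95": "logp95", "abundance": "abund"})
    return pops
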