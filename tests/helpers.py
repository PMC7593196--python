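"""Shared builders for the test-suite."""

import numpy as np
import pandas as pd


def make_populations(rng, n_species=5, n_sites=12, slope=0.0, noise=0.3):
    """Random populations table for model-fitting tests.

    ``slope`` is a true abundance effect; each species gets its own
    random intercept, matching the mixed-model structure.
    """
    sst = rng.uniform(15, 29, n_sites)
    npp = rng.uniform(200, 800, n_sites)
    rows = []
    for i in range(n_species):
        ab = rng.uniform(0, 1, n_sites)
        y = 10 + slope * ab + rng.normal(0, noise, n_sites) + 0.3 * rng.normal()
        for j in range(n_sites):
            rows.append((f"sp{i}", f"s{j}", y[j], sst[j], npp[j], ab[j]))
    return pd.DataFrame(rows, columns=["species", "site_id", "logp95", "sst", "npp", "abund"])
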