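"""Generator contracts: determinism, dependence structure, niche
normalization, exact order-statistic truth, and collector-bias direction."""

import numpy as np
import pandas as pd
import pytest

import foramsize as fs
from foramsize.config import Z95
from foramsize.simulate import BIASED_COLLECTION, simulate_assemblage


def test_same_seed_gives_bit_identical_tables():
    cfg = fs.SimulationConfig(n_species=3, n_sites=8, individuals_per_site=6, seed=77)
    a = fs.simulate_dataset(cfg)
    b = fs.simulate_dataset(fs.SimulationConfig(n_species=3, n_sites=8,
                                                individuals_per_site=6, seed=77))
    for ta, tb in [(a.sites, b.sites), (a.specimens, b.specimens),
                   (a.specimens_biased, b.specimens_biased),
                   (a.assemblage, b.assemblage), (a.truth, b.truth)]:
        pd.testing.assert_frame_equal(ta, tb)
    pd.testing.assert_frame_equal(a.grids["sst"], b.grids["sst"])


def test_written_tables_roundtrip_identically(tmp_path):
    cfg = fs.SimulationConfig(n_species=2, n_sites=5, individuals_per_site=4, seed=5)
    p1, p2 = tmp_path / "a", tmp_path / "b"
    fs.simulate_dataset(cfg).write(p1)
    fs.simulate_dataset(cfg).write(p2)
    for name in ("sites.csv", "specimens_bulk.csv", "specimens_museum.csv",
                 "assemblage.csv", "truth.csv", "sim_config.yaml"):
        assert (p1 / name).read_bytes() == (p2 / name).read_bytes()


def test_config_yaml_roundtrip(tmp_path):
    cfg = fs.SimulationConfig(n_species=3, n_sites=7, seed=9)
    cfg.to_yaml(tmp_path / "c.yaml")
    back = fs.SimulationConfig.from_yaml(tmp_path / "c.yaml")
    assert back.to_dict() == cfg.to_dict()


@pytest.mark.parametrize("bad", [
    dict(n_species=0), dict(n_sites=2), dict(site_noise_sd=0.0),
    dict(individual_log_sd=-1.0), dict(lat_range=(40.0, -40.0)),
    dict(lat_range=(-95.0, 40.0)), dict(individuals_per_site=0),
    dict(collector_pool_factor=0.5),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        fs.SimulationConfig(**bad)


def test_sst_npp_correlation_converges_to_target():
    # sampling check over 20 seeds at n_sites = 500
    corrs = []
    for seed in range(20):
        cfg = fs.SimulationConfig(n_sites=500, n_species=1, seed=seed)
        sites, _ = fs.simulate_environment(cfg)
        corrs.append(np.corrcoef(sites["sst"], sites["npp"])[0, 1])
    corrs = np.asarray(corrs)
    assert ((corrs > 0.3) & (corrs < 0.5)).all()


def test_zero_target_correlation_gives_independence():
    cfg = fs.SimulationConfig(n_sites=500, n_species=1, target_sst_npp_corr=0.0, seed=4)
    sites, _ = fs.simulate_environment(cfg)
    assert abs(np.corrcoef(sites["sst"], sites["npp"])[0, 1]) < 0.15


def test_sst_declines_with_absolute_latitude():
    cfg = fs.SimulationConfig(n_sites=400, n_species=1, seed=2)
    sites, _ = fs.simulate_environment(cfg)
    tropical = sites[np.abs(sites["latitude"]) < 10]["sst"].mean()
    edge = sites[np.abs(sites["latitude"]) > 30]["sst"].mean()
    assert tropical > edge + 5


def test_single_species_abundance_is_one_everywhere(small_dataset):
    cfg = fs.SimulationConfig(n_species=1, n_sites=10, seed=1)
    sites, _ = fs.simulate_environment(cfg)
    ab = fs.simulate_abundances(sites, cfg)
    assert np.allclose(ab["abundance"], 1.0)


def test_two_equal_niches_split_evenly_at_midpoint():
    cfg = fs.SimulationConfig(n_species=2, n_sites=3, seed=1,
                              sst_niche_centers=[20.0, 26.0], sst_niche_widths=4.0)
    sites = pd.DataFrame({"site_id": ["a", "b", "c"],
                          "latitude": [0.0, 1.0, 2.0], "longitude": [0.0, 1.0, 2.0],
                          "sst": [23.0, 23.0, 23.0], "npp": [500.0] * 3})
    ab = fs.simulate_abundances(sites, cfg)
    assert np.allclose(ab["abundance"], 0.5)


def test_abundances_sum_to_one_per_site(small_dataset):
    ds = small_dataset
    sums = ds.assemblage.groupby("sample_id")["abundance"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_vanishing_niches_raise_rather_than_nan():
    cfg = fs.SimulationConfig(n_species=2, n_sites=3, seed=1,
                              sst_niche_centers=[-500.0, 900.0],
                              sst_niche_widths=[0.5, 0.5])
    sites = pd.DataFrame({"site_id": ["a"], "latitude": [0.0], "longitude": [0.0],
                          "sst": [25.0], "npp": [500.0]})
    with pytest.raises(FloatingPointError):
        fs.simulate_abundances(sites, cfg)


def test_degenerate_individual_noise_pins_individuals_to_target():
    cfg = fs.SimulationConfig(n_species=2, n_sites=4, individuals_per_site=5,
                              individual_log_sd=1e-9, seed=3)
    sites, _ = fs.simulate_environment(cfg)
    spec, truth = fs.simulate_specimens(sites, cfg)
    logs = np.log(spec["area"])
    t = truth.set_index(["species", "site_id"])["target_logp95"]
    targets = [t.loc[(r.species, r.site_id)] for r in spec.itertuples()]
    assert np.allclose(logs, targets, atol=1e-6)


def test_sample_p95_converges_to_target_at_large_n():
    cfg = fs.SimulationConfig(n_species=1, n_sites=3, individuals_per_site=10_000,
                              site_noise_sd=1e-9, seed=8)
    sites, _ = fs.simulate_environment(cfg)
    spec, truth = fs.simulate_specimens(sites, cfg)
    for (sp, site), grp in spec.groupby(["species", "site_id"]):
        target = truth.set_index(["species", "site_id"]).loc[(sp, site), "target_logp95"]
        p95 = np.quantile(np.log(grp["area"]), 0.95)
        assert abs(p95 - target) < 0.02


def test_sample_p95_error_scales_like_order_statistic_variance():
    # SE of the sample 95th percentile ~ sigma*sqrt(p(1-p)/n)/phi(z95)
    cfg0 = fs.SimulationConfig(n_species=1, n_sites=3, seed=0)
    sigma = cfg0.individual_log_sd
    phi = np.exp(-Z95 ** 2 / 2) / np.sqrt(2 * np.pi)
    rng = np.random.default_rng(99)
    for n in (50, 500, 5000):
        errs = []
        for _ in range(200):
            logs = rng.normal(-Z95 * sigma, sigma, n)
            errs.append(np.quantile(logs, 0.95))
        se_emp = np.std(errs)
        se_theory = sigma * np.sqrt(0.95 * 0.05 / n) / phi
        assert 0.5 * se_theory < se_emp < 2.0 * se_theory


def test_truth_regression_recovers_pure_sst_slope_exactly():
    cfg = fs.SimulationConfig(n_species=1, n_sites=30, site_noise_sd=1e-12,
                              size_coefficients=[[10.0, 0.07, 0.0, 0.0]], seed=6)
    sites, _ = fs.simulate_environment(cfg)
    _, truth = fs.simulate_specimens(sites, cfg)
    merged = truth.merge(sites, on="site_id")
    slope = np.polyfit(merged["sst"], merged["target_logp95"], 1)[0]
    assert slope == pytest.approx(0.07, abs=1e-6)


def test_flat_retention_keeps_about_half():
    cfg = fs.SimulationConfig(n_species=2, n_sites=10, individuals_per_site=200,
                              bias_steepness=1e9, seed=13)
    sites, _ = fs.simulate_environment(cfg)
    spec, _ = fs.simulate_specimens(sites, cfg)
    kept = fs.apply_collector_bias(spec, cfg)
    frac = len(kept) / len(spec)
    assert 0.45 < frac < 0.55
    assert (kept["collection"] == BIASED_COLLECTION).all()


def test_retained_specimens_are_larger_on_average(small_dataset):
    ds = small_dataset
    spec, _ = fs.simulate_specimens(ds.sites, ds.config)
    kept = fs.apply_collector_bias(spec, ds.config)
    assert np.log(kept["area"]).mean() >= np.log(spec["area"]).mean()


def test_assemblage_has_one_record_at_each_site(small_dataset):
    ds = small_dataset
    site_coords = set(zip(ds.sites["latitude"], ds.sites["longitude"]))
    rec_coords = set(zip(ds.assemblage["latitude"], ds.assemblage["longitude"]))
    assert site_coords <= rec_coords


def test_degenerate_lat_range_rejected():
    with pytest.raises(ValueError):
        fs.SimulationConfig(n_sites=5, lat_range=(10.0, 10.0))


def test_assemblage_jitter_stays_within_drift_radius():
    cfg = fs.SimulationConfig(n_species=2, n_sites=6, drift_km=150.0, seed=21)
    sites, _ = fs.simulate_environment(cfg)
    rec = simulate_assemblage(sites, cfg)
    coords = rec[["latitude", "longitude"]].drop_duplicates()
    for _, s in sites.iterrows():
        d = fs.geodesic_km_many(s["latitude"], s["longitude"],
                                coords["latitude"].to_numpy(),
                                coords["longitude"].to_numpy())
        assert (np.sort(d)[:cfg.records_per_site] <= cfg.drift_km * 1.1 + 1e-6).all()
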