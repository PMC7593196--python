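"""Gaussian ML fits, AICc, candidate comparison and the mixed-model LRT."""

import numpy as np
import pandas as pd
import pytest

import foramsize as fs
from foramsize.modelsel import RankDeficientDesign, _fit_mixed, candidate_df

from helpers import make_populations


def _brute_force_loglik(y, X, span=3.0, steps=161):
    """Independent oracle: coarse grid search over coefficients
    minimizing RSS, refined once, then the closed-form Gaussian ML
    log-likelihood at the grid optimum."""
    y = np.asarray(y, float)
    n, p = X.shape
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)  # centre of the grid only
    best = None
    grids = [np.linspace(b - span, b + span, steps) for b in beta0]
    if p == 1:
        for b0 in grids[0]:
            r = y - X[:, 0] * b0
            rss = r @ r
            if best is None or rss < best[0]:
                best = (rss, [b0])
    else:
        for b0 in grids[0]:
            for b1 in grids[1]:
                r = y - X[:, 0] * b0 - X[:, 1] * b1
                rss = r @ r
                if best is None or rss < best[0]:
                    best = (rss, [b0, b1])
    rss = best[0]
    return -n / 2 * (np.log(2 * np.pi * rss / n) + 1)


def test_loglik_closed_form_when_rss_is_n_over_2pi():
    # RSS = n/(2*pi) makes logLik collapse to -n/2
    n = 4
    d = np.sqrt(1 / (2 * np.pi))
    y = np.array([1 + d, 1 - d, 1 + d, 1 - d])
    X = np.ones((n, 1))
    _, ll, rss = fs.ols_ml_loglik(y, X)
    assert rss == pytest.approx(n / (2 * np.pi))
    assert ll == pytest.approx(-n / 2)


def test_hand_worked_three_point_regression():
    y = np.array([0.0, 1.0, 1.0])
    X = np.column_stack([np.ones(3), np.array([0.0, 1.0, 2.0])])
    beta, ll, rss = fs.ols_ml_loglik(y, X)
    assert beta[1] == pytest.approx(0.5)
    assert beta[0] == pytest.approx(1 / 6)
    assert rss == pytest.approx(1 / 6)
    assert ll == pytest.approx(-1.5 * (np.log(2 * np.pi * (1 / 6) / 3) + 1))
    # independent check via statsmodels' Gaussian ML log-likelihood
    import statsmodels.api as sm
    assert ll == pytest.approx(sm.OLS(y, X).fit().llf, abs=1e-10)


def test_intercept_only_fits_the_mean():
    rng = np.random.default_rng(0)
    y = rng.normal(5, 1, 20)
    beta, _, rss = fs.ols_ml_loglik(y, np.ones((20, 1)))
    assert beta[0] == pytest.approx(y.mean())
    assert rss == pytest.approx(((y - y.mean()) ** 2).sum())


def test_loglik_matches_brute_force_oracle_on_small_instances():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(5, 12))
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n) + x * rng.normal()
        X = np.column_stack([np.ones(n), x])
        _, ll, _ = fs.ols_ml_loglik(y, X)
        assert ll >= _brute_force_loglik(y, X) - 1e-6
        assert ll == pytest.approx(_brute_force_loglik(y, X), abs=0.05)


def test_rank_deficient_design_raises_naming_terms():
    n = 10
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    with pytest.raises(RankDeficientDesign, match="terms"):
        fs.ols_ml_loglik(np.arange(n, dtype=float), X, term_names=("intercept", "a", "b"))


def test_perfect_fit_rejected():
    x = np.arange(5, dtype=float)
    X = np.column_stack([np.ones(5), x])
    with pytest.raises(ValueError, match="RSS"):
        fs.ols_ml_loglik(2 * x + 1, X)


def test_aicc_formula_and_large_n_limit():
    assert fs.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
    assert fs.aicc(-5.0, 3, 10_000_000) == pytest.approx(10 + 6, abs=1e-4)
    with pytest.raises(ValueError):
        fs.aicc(0.0, 3, 4)


def test_aicc_penalizes_parameters_monotonically():
    vals = [fs.aicc(-10.0, k, 40) for k in range(2, 7)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_candidate_parameter_counts():
    expected = {"null": 2, "sst": 3, "sst2": 4, "pp": 3, "abund": 3,
                "sst+pp": 4, "sst+abund": 4, "sst:pp": 5, "sst2+pp": 5, "sst2:pp": 6}
    assert {lab: candidate_df(lab) for lab in fs.CANDIDATE_TERMS} == expected


def test_best_model_has_zero_delta_and_top_weight():
    pops = make_populations(np.random.default_rng(1), n_species=1, n_sites=20)
    res = fs.select_models(pops)
    t = res.table
    assert t["delta_aicc"].iloc[0] == 0.0
    assert (t["delta_aicc"] >= 0).all()
    assert (t["delta_aicc"] == 0).sum() == 1
    assert t["weight"].iloc[0] == t["weight"].max()
    assert t["weight"].sum() == pytest.approx(1.0, abs=1e-9)


def test_equal_fits_share_the_weight():
    rng = np.random.default_rng(2)
    n = 15
    sst = rng.normal(22, 4, n)
    df = pd.DataFrame({"species": "sp", "logp95": rng.normal(10, 0.3, n),
                       "sst": sst, "npp": sst, "abund": rng.uniform(0, 1, n)})
    res = fs.select_models(df, candidates=("sst", "pp"))
    assert np.allclose(res.table["weight"], 0.5)
    assert set(res.plausible) == {"sst", "pp"}


def test_intercept_only_model_has_zero_adjusted_r2():
    pops = make_populations(np.random.default_rng(3), n_species=1, n_sites=25)
    res = fs.select_models(pops, candidates=("null",))
    assert res.table["r2_adj"].iloc[0] == pytest.approx(0.0)


def test_infeasible_candidates_skipped_with_warning():
    pops = make_populations(np.random.default_rng(4), n_species=1, n_sites=6)
    with pytest.warns(UserWarning, match="infeasible"):
        res = fs.select_models(pops)
    assert "sst2:pp" in res.skipped          # k=6 needs n > 7
    assert "null" in res.table["label"].tolist()


def test_nested_models_never_lose_loglik():
    rng = np.random.default_rng(6)
    for _ in range(10):
        pops = make_populations(rng, n_species=1, n_sites=15)
        res = fs.select_models(pops)
        ll = res.table.set_index("label")["loglik"]
        assert ll["sst2"] >= ll["sst"] - 1e-9
        assert ll["sst"] >= ll["null"] - 1e-9
        assert ll["sst2:pp"] >= ll["sst2+pp"] - 1e-9 >= ll["sst+pp"] - 2e-9


def test_centering_option_changes_design_but_not_null_fit():
    pops = make_populations(np.random.default_rng(7), n_species=1, n_sites=20)
    plain = fs.select_models(pops, candidates=("null", "sst"))
    centred = fs.select_models(pops, candidates=("null", "sst"), center=True)
    ll_p = plain.table.set_index("label")["loglik"]
    ll_c = centred.table.set_index("label")["loglik"]
    assert ll_p["null"] == pytest.approx(ll_c["null"])
    assert ll_p["sst"] == pytest.approx(ll_c["sst"])  # affine reparametrization


def test_mixed_lrt_zero_when_models_identical():
    pops = make_populations(np.random.default_rng(8), n_species=4, n_sites=10)
    a = _fit_mixed(pops, "logp95", with_abundance=False)
    b = _fit_mixed(pops, "logp95", with_abundance=False)
    assert 2 * (a.llf - b.llf) == pytest.approx(0.0, abs=1e-10)


def test_mixed_lrt_detects_a_strong_abundance_effect():
    rng = np.random.default_rng(9)
    small = fs.lrt_abundance_mixed(make_populations(rng, n_species=4, n_sites=8,
                                                    slope=1.0, noise=0.25))
    big = fs.lrt_abundance_mixed(make_populations(rng, n_species=8, n_sites=30,
                                                  slope=1.0, noise=0.25))
    assert big.chi2 > small.chi2
    assert big.p_value < 1e-3
    assert big.coef_abundance > 0


def test_mixed_lrt_requires_replication():
    pops = make_populations(np.random.default_rng(10), n_species=1, n_sites=10)
    with pytest.raises(ValueError, match="2 species"):
        fs.lrt_abundance_mixed(pops)
    two = make_populations(np.random.default_rng(11), n_species=2, n_sites=5)
    with pytest.raises(ValueError, match="populations"):
        fs.lrt_abundance_mixed(two.iloc[:6])  # second species has a single row


def test_strong_truth_signal_excludes_null_model(truth_populations):
    # every species' sizes are generated with a clear SST effect: the
    # intercept-only model should never be among the plausible set
    pops = truth_populations
    for _, grp in pops.groupby("species"):
        res = fs.select_models(grp)
        assert "null" not in res.plausible
        assert res.table.set_index("label")["delta_aicc"]["null"] > 2.0
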