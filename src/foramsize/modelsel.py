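"""AICc multimodel inference for population size vs environment.

For each species, the response is the natural log of the population
95th-percentile shell area and the candidate set comprises ten linear
models in mean annual SST, NPP and local relative abundance (linear and
quadratic SST terms and the SST x NPP interaction).  Fits are Gaussian
maximum likelihood (equivalently OLS), compared by AICc with Akaike
weights over the full fitted set; models within two AICc units of the
best (strict inequality) form the "equally plausible" set.  A
random-intercept mixed model provides the cross-species likelihood
ratio test of the abundance effect.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANDIDATE_TERMS",
    "design_matrix",
    "ols_ml_loglik",
    "aicc",
    "select_models",
    "ModelSelectionResult",
    "lrt_abundance_mixed",
    "MixedModelResult",
]

logger = logging.getLogger(__name__)

#: candidate label -> design terms beyond the intercept.  Interaction
#: labels include their main effects; with k = coefficients + 1 (the
#: residual variance) the parameter counts are
#: null 2, sst 3, sst2 4, pp 3, abund 3, sst+pp 4, sst+abund 4,
#: sst:pp 5, sst2+pp 5, sst2:pp 6.
CANDIDATE_TERMS: dict[str, tuple[str, ...]] = {
    "null": (),
    "sst": ("sst",),
    "sst2": ("sst", "sst^2"),
    "pp": ("pp",),
    "abund": ("abund",),
    "sst+pp": ("sst", "pp"),
    "sst+abund": ("sst", "abund"),
    "sst:pp": ("sst", "pp", "sst*pp"),
    "sst2+pp": ("sst", "sst^2", "pp"),
    "sst2:pp": ("sst", "sst^2", "pp", "sst*pp"),
}


def candidate_df(label: str) -> int:
    """Parameter count k of a candidate: coefficients (incl. intercept)
    plus the residual variance."""
    return len(CANDIDATE_TERMS[label]) + 2


def _term_column(term: str, data: pd.DataFrame) -> np.ndarray:
    sst = data["sst"].to_numpy(float) if "sst" in data else None
    if term == "sst":
        return sst
    if term == "sst^2":
        return sst ** 2
    if term == "pp":
        return data["npp"].to_numpy(float)
    if term == "abund":
        return data["abund"].to_numpy(float)
    if term == "sst*pp":
        return sst * data["npp"].to_numpy(float)
    raise KeyError(f"unknown design term {term!r}")


def design_matrix(label: str, data: pd.DataFrame, center: bool = False):
    """Design matrix (with leading intercept column) for a candidate.

    ``center`` subtracts covariate means before forming powers and
    products; off by default (covariates enter untransformed).
    """
    terms = CANDIDATE_TERMS[label]
    d = data
    if center:
        d = data.copy()
        for c in ("sst", "npp", "abund"):
            if c in d:
                d[c] = d[c] - d[c].mean()
    cols = [np.ones(len(data))] + [_term_column(t, d) for t in terms]
    return np.column_stack(cols), ("intercept",) + terms


class RankDeficientDesign(ValueError):
    pass


def ols_ml_loglik(y: np.ndarray, X: np.ndarray, term_names=None):
    """Gaussian maximum-likelihood fit of ``y`` on design ``X``.

    Returns ``(coefficients, loglik, rss)`` with
    ``loglik = -n/2 * (ln(2*pi*RSS/n) + 1)`` (variance profiled at its
    ML estimate RSS/n), the form whose -2*logLik feeds AICc directly.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than coefficients (n={n}, p={p})")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in response or design")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = term_names if term_names is not None else [f"x{i}" for i in range(p)]
        raise RankDeficientDesign(
            f"rank-deficient design (rank {rank} < {p} columns); terms: {tuple(names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("perfect fit (RSS = 0): Gaussian likelihood degenerate")
    loglik = -n / 2.0 * (math.log(2.0 * math.pi * rss / n) + 1.0)
    return beta, loglik, rss


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction:
    ``-2*logLik + 2k + 2k(k+1)/(n-k-1)``.  Requires ``n > k + 1``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class ModelSelectionResult:
    """Per-species candidate comparison.

    ``table`` has one row per fitted candidate: label, k, n, loglik,
    aicc, delta_aicc, weight, r2_adj plus the coefficient estimates;
    sorted by AICc.  ``plausible`` lists labels with delta_aicc < the
    threshold (strict).
    """

    table: pd.DataFrame
    plausible: tuple[str, ...]
    delta_threshold: float
    skipped: tuple[str, ...] = ()

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["label"])


def select_models(
    data: pd.DataFrame,
    response: str = "logp95",
    candidates=None,
    delta_threshold: float = 2.0,
    center: bool = False,
) -> ModelSelectionResult:
    """Fit the candidate set and compare by AICc.

    ``data`` needs one row per population with the response column and
    the covariates each candidate uses (``sst``, ``npp``, ``abund``).
    Candidates infeasible at the available n (n <= k+1) are skipped with
    a warning.  Akaike weights are normalized over the fitted set;
    adjusted R^2 is ``1 - (1 - R^2) (n - 1)/(n - p - 1)`` with p the
    number of non-intercept coefficients.
    """
    if candidates is None:
        candidates = tuple(CANDIDATE_TERMS)
    unknown = [c for c in candidates if c not in CANDIDATE_TERMS]
    if unknown:
        raise KeyError(f"unknown candidate label(s): {unknown}")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    skipped = []
    for label in candidates:
        k = candidate_df(label)
        if n <= k + 1:
            skipped.append(label)
            warnings.warn(f"candidate {label!r} infeasible at n={n} (k={k}); skipped",
                          stacklevel=2)
            continue
        X, names = design_matrix(label, data, center=center)
        try:
            beta, ll, rss = ols_ml_loglik(y, X, term_names=names)
        except RankDeficientDesign as e:
            skipped.append(label)
            warnings.warn(f"candidate {label!r} skipped: {e}", stacklevel=2)
            continue
        p = X.shape[1] - 1
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)
        row = {"label": label, "k": k, "n": n, "loglik": ll,
               "aicc": aicc(ll, k, n), "r2_adj": r2_adj}
        row.update({f"beta_{nm}": b for nm, b in zip(names, beta)})
        rows.append(row)
    if not rows:
        raise ValueError(f"no candidate model is feasible at n={n}")
    table = pd.DataFrame(rows)
    best = table["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    rel = np.exp(-table["delta_aicc"].to_numpy() / 2.0)
    table["weight"] = rel / rel.sum()
    table = table.sort_values(["aicc", "label"], kind="mergesort").reset_index(drop=True)
    plausible = tuple(table.loc[table["delta_aicc"] < delta_threshold, "label"])
    front = ["label", "k", "n", "loglik", "aicc", "delta_aicc", "weight", "r2_adj"]
    table = table[front + [c for c in table.columns if c not in front]]
    return ModelSelectionResult(table=table, plausible=plausible,
                                delta_threshold=delta_threshold, skipped=tuple(skipped))


@dataclass
class MixedModelResult:
    """Random-intercept LRT of the abundance effect across species."""

    coef_abundance: float
    loglik_full: float
    loglik_null: float
    chi2: float
    df: int
    p_value: float
    re_variance: float
    boundary: bool

    def __str__(self):
        flag = " (variance component on boundary)" if self.boundary else ""
        return (f"abundance effect {self.coef_abundance:+.4f}, "
                f"chi2({self.df}) = {self.chi2:.2f}, p = {self.p_value:.3g}{flag}")


def _fit_mixed(data: pd.DataFrame, response: str, with_abundance: bool):
    import statsmodels.api as sm

    exog = pd.DataFrame({"intercept": np.ones(len(data))})
    if with_abundance:
        exog["abund"] = data["abund"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data[response].to_numpy(float), exog.to_numpy(),
                           groups=data["species"].to_numpy())
        fit = model.fit(reml=False)
    return fit


def lrt_abundance_mixed(data: pd.DataFrame, response: str = "logp95") -> MixedModelResult:
    """ML likelihood-ratio test of ``response ~ abundance + (1|species)``
    against the random-intercept-only null.

    Fitted by maximum likelihood (not REML) so the fixed-effect
    comparison is valid; chi-square has 1 degree of freedom.  A
    random-intercept variance estimated at (or squashed against) zero
    is reported via ``boundary`` rather than hidden.
    """
    counts = data.groupby("species").size()
    if len(counts) < 2:
        raise ValueError("mixed-model LRT needs >= 2 species")
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise ValueError(f"every species needs >= 2 populations; too few for: {few}")
    full = _fit_mixed(data, response, with_abundance=True)
    null = _fit_mixed(data, response, with_abundance=False)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    re_var = float(np.asarray(full.cov_re)[0, 0])
    resid_var = float(full.scale)
    boundary = re_var < 1e-8 * max(resid_var, 1e-12)
    return MixedModelResult(
        coef_abundance=float(full.fe_params[1]),
        loglik_full=float(full.llf),
        loglik_null=float(null.llf),
        chi2=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        re_variance=re_var,
        boundary=boundary,
    )
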