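"""Regression of F_roh on educational attainment with permutation inference
and mediation analysis.

Three pieces:

* plain OLS with standardised coefficients (the scale on which genomic
  inbreeding effects are conventionally reported);
* a permutation test for the R^2 change when one predictor is added to a
  nested model — the outcome is shuffled across subjects, which respects
  its non-normal distribution, and the observed increment is ranked among
  the shuffled ones;
* the Sobel test of an indirect effect alpha*beta (EA -> parental
  birthplace distance -> F_roh) together with the full-mediation test of
  the direct effect tau' once the mediator is in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "PermutationResult",
    "MediationResult",
    "ols",
    "r2_change_perm_test",
    "sobel_test",
]


@dataclass
class RegressionResult:
    params: pd.Series  # unstandardised slopes (and intercept)
    std_betas: pd.Series  # standardised slopes, no intercept
    pvalues: pd.Series
    r2: float
    n: int


@dataclass
class PermutationResult:
    r2_change: float
    empirical_p: float
    n_perm: int
    seed: int | None


@dataclass
class MediationResult:
    alpha: float
    alpha_se: float
    beta: float
    beta_se: float
    beta_p: float
    tau_prime: float
    tau_prime_p: float
    tau: float
    sobel_z: float
    sobel_p: float
    n: int


def _design(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    sds = X.std(ddof=0)
    const = sds[sds == 0].index.tolist()
    if const:
        raise ValueError(f"constant predictor column(s) besides intercept: {const}")
    return X


def _name_collinear(X: pd.DataFrame) -> list:
    """Columns whose genotype is (near-)exactly predicted by the others."""
    bad = []
    Z = (X - X.mean()) / X.std(ddof=0)
    arr = Z.to_numpy()
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
        resid = arr[:, j] - others @ coef
        if np.var(resid) < 1e-10:
            bad.append(name)
    return bad


def ols(y, X) -> RegressionResult:
    """Least-squares fit of ``y`` on ``X`` plus an intercept.

    Standardised betas are the slopes of the fit on z-scored outcome and
    predictors; their t-based p-values equal the unstandardised ones.
    Rank deficiency is rejected with the offending columns named.
    """
    X = _design(X)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != len(X):
        raise ValueError("y must be 1-D and match X rows")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.std(y) == 0:
        raise ValueError("outcome is constant")
    exog = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: {_name_collinear(X)}")
    fit = sm.OLS(y, exog).fit()
    std_betas = fit.params.drop("const") * X.std(ddof=0) / np.std(y)
    return RegressionResult(
        params=fit.params,
        std_betas=std_betas,
        pvalues=fit.pvalues.drop("const"),
        r2=float(fit.rsquared),
        n=n,
    )


def _proj_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of [1, X]."""
    n = X.shape[0]
    M = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(M)
    keep = np.abs(np.diag(R)) > 1e-10 * np.abs(R[0, 0])
    return Q[:, keep]


def r2_change_perm_test(
    y,
    X_base,
    x_new,
    n_perm: int = 100_000,
    seed: int | None = None,
    *,
    convention: str = "add_one",
    chunk: int = 2_000,
) -> PermutationResult:
    """Permutation test of the R^2 increment from adding ``x_new``.

    The observed increment is R^2(base + new) - R^2(base).  The null
    distribution re-computes the increment after randomly shuffling the
    outcome across subjects ``n_perm`` times.  ``convention`` controls the
    empirical p-value: ``"add_one"`` (default) uses
    (#{null >= observed} + 1) / (n_perm + 1), which can never return an
    exact zero; ``"rank"`` uses #{null >= observed} / n_perm, the plain
    rank-among-nulls convention under which extreme results are reported
    as p below 1/n_perm.
    """
    if n_perm == 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; empirical p is unstable")
    if convention not in ("add_one", "rank"):
        raise ValueError("convention must be 'add_one' or 'rank'")
    y = np.asarray(y, dtype=float)
    Xb = pd.DataFrame(X_base).to_numpy(dtype=float)
    xn = np.asarray(x_new, dtype=float).reshape(-1)
    if not (len(y) == len(Xb) == len(xn)):
        raise ValueError("y, X_base and x_new must have equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("outcome is constant")
    Qb = _proj_basis(Xb)
    Qf = _proj_basis(np.column_stack([Xb, xn]))
    obs = (np.sum((Qf.T @ y) ** 2) - np.sum((Qb.T @ y) ** 2)) / sst

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, y.size)), axis=1)
        Yp = y[idx].T  # (n, b)
        null = (np.sum((Qf.T @ Yp) ** 2, axis=0) - np.sum((Qb.T @ Yp) ** 2, axis=0)) / sst
        exceed += int(np.sum(null >= obs - 1e-15))
        done += b
    if convention == "add_one":
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return PermutationResult(
        r2_change=float(obs), empirical_p=float(p), n_perm=n_perm, seed=seed
    )


def sobel_test(x, m, y, covariates=None) -> MediationResult:
    """Sobel test of the indirect effect of ``x`` on ``y`` through ``m``.

    Fits two regressions on listwise-complete cases:

        m ~ x + covariates            -> alpha
        y ~ x + m + covariates        -> tau' (direct) and beta

    The indirect effect alpha*beta is tested with the classic second-order
    Sobel standard error; the full-mediation test is the t-test of tau'.
    The total effect tau (from y ~ x + covariates) is returned as well and
    satisfies tau = tau' + alpha*beta exactly on the same sample.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(index=range(len(x)))
    cov = cov.reset_index(drop=True).astype(float)
    mask = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    if len(cov.columns):
        mask &= ~cov.isna().any(axis=1).to_numpy()
    x, m, y = x[mask], m[mask], y[mask]
    cov = cov.loc[mask].reset_index(drop=True)
    if np.std(m) == 0:
        raise ValueError("mediator has zero variance")

    def fit(dep, cols: dict):
        X = pd.DataFrame(cols)
        if len(cov.columns):
            X = pd.concat([X, cov], axis=1)
        exog = sm.add_constant(X)
        return sm.OLS(dep, exog).fit()

    f_alpha = fit(m, {"x": x})
    f_full = fit(y, {"x": x, "m": m})
    f_total = fit(y, {"x": x})

    alpha = float(f_alpha.params["x"])
    alpha_se = float(f_alpha.bse["x"])
    beta = float(f_full.params["m"])
    beta_se = float(f_full.bse["m"])
    tau_prime = float(f_full.params["x"])
    tau = float(f_total.params["x"])
    se = np.sqrt(beta**2 * alpha_se**2 + alpha**2 * beta_se**2)
    z = alpha * beta / se if se > 0 else 0.0
    return MediationResult(
        alpha=alpha,
        alpha_se=alpha_se,
        beta=beta,
        beta_se=beta_se,
        beta_p=float(f_full.pvalues["m"]),
        tau_prime=tau_prime,
        tau_prime_p=float(f_full.pvalues["x"]),
        tau=tau,
        sobel_z=float(z),
        sobel_p=float(2.0 * stats.norm.sf(abs(z))),
        n=int(x.size),
    )
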