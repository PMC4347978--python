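"""Ancestry PCA and the moderated PC-geography correlation model.

Ancestry-informative principal components are computed from the
standardised genotype matrix (each SNP centred at twice its allele
frequency and scaled by the binomial standard deviation), and their
association with geographic coordinates is allowed to vary with parental
educational level g through a linear trend on the correlation scale:

    rho_g = rho0 + g * rho1,   g in {0, 1, 2, 3}

fitted by maximum likelihood on a bivariate normal with shared means and
variances across groups; the null hypothesis rho1 = 0 is assessed with a
likelihood-ratio test on one degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCScores", "ModCorrFit", "standardized_pca", "corr_pc_geo", "moderated_correlation_fit"]

_RHO_BOUND = 0.999


@dataclass
class PCScores:
    scores: np.ndarray  # (n_samples, k), unit-norm eigenvectors
    eigenvalues: np.ndarray  # (k,), non-increasing
    loadings: np.ndarray  # (n_kept_snps, k)
    kept_snps: np.ndarray  # indices into the input SNP columns


@dataclass
class ModCorrFit:
    rho0: float
    rho1: float
    rho_by_group: dict
    rho1_se: float
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    p: float
    df: int
    at_bound: bool
    n_by_group: dict


# ---------------------------------------------------------------------------
# PCA


def standardized_pca(G: GenotypeMatrix, k: int) -> PCScores:
    """Top-``k`` principal components of the standardised genotype matrix.

    Missing calls are mean-imputed per SNP; monomorphic SNPs are dropped
    (logged).  Each SNP is centred by 2*p_hat and scaled by
    sqrt(2*p_hat*(1-p_hat)); scores are the leading eigenvectors of the
    sample covariance of standardised genotypes, computed by exact
    eigendecomposition of the n x n kernel.
    """
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])
    p_hat = col_mean / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    if (~keep).any():
        logger.info("standardized_pca: dropping %d monomorphic SNPs", int((~keep).sum()))
    kept = np.flatnonzero(keep)
    n, m = calls.shape[0], kept.size
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n-1, #SNPs) = {min(n - 1, m)}")
    p = p_hat[kept]
    Z = (calls[:, kept] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = (Z @ Z.T) / m
    w, v = np.linalg.eigh(K)
    order = np.argsort(w)[::-1][:k]
    eigvals = w[order]
    scores = v[:, order]
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = Z.T @ scores / np.sqrt(np.maximum(n * eigvals, 1e-300))
    return PCScores(scores=scores, eigenvalues=eigvals, loadings=loadings, kept_snps=kept)


def corr_pc_geo(pc, coordinate) -> float:
    """Pearson correlation of a PC score vector with a coordinate vector
    (complete cases only)."""
    pc = np.asarray(pc, dtype=float)
    coord = np.asarray(coordinate, dtype=float)
    if pc.shape != coord.shape or pc.ndim != 1:
        raise ValueError("pc and coordinate must be 1-D of equal length")
    mask = ~(np.isnan(pc) | np.isnan(coord))
    pc, coord = pc[mask], coord[mask]
    if pc.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(pc) == 0 or np.std(coord) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(pc, coord)[0, 1])


# ---------------------------------------------------------------------------
# Moderated correlation model


def _group_stats(pc, coord, groups):
    out = {}
    for g in np.unique(groups):
        x = pc[groups == g]
        y = coord[groups == g]
        out[int(g)] = (x, y)
    return out


def _bvn_negll_shared(theta, data):
    """Negative log-likelihood, shared means/variances, rho_g = rho0 + g*rho1."""
    mx, my, lsx, lsy, rho0, rho1 = theta
    if abs(lsx) > 20 or abs(lsy) > 20:
        return 1e12
    sx, sy = np.exp(lsx), np.exp(lsy)
    nll = 0.0
    for g, (x, y) in data.items():
        rho = rho0 + g * rho1
        if not -_RHO_BOUND < rho < _RHO_BOUND:
            return 1e12
        zx = (x - mx) / sx
        zy = (y - my) / sy
        q = (zx**2 - 2 * rho * zx * zy + zy**2) / (1 - rho**2)
        nll += 0.5 * np.sum(q) + x.size * (
            np.log(2 * np.pi) + lsx + lsy + 0.5 * np.log1p(-(rho**2))
        )
    return nll


def _bvn_negll_free(theta, data):
    """Negative log-likelihood with per-group means/variances."""
    groups = sorted(data)
    rho0, rho1 = theta[-2:]
    nll = 0.0
    for i, g in enumerate(groups):
        mx, my, lsx, lsy = theta[4 * i : 4 * i + 4]
        rho = rho0 + g * rho1
        if not -_RHO_BOUND < rho < _RHO_BOUND or abs(lsx) > 20 or abs(lsy) > 20:
            return 1e12
        x, y = data[g]
        sx, sy = np.exp(lsx), np.exp(lsy)
        zx = (x - mx) / sx
        zy = (y - my) / sy
        q = (zx**2 - 2 * rho * zx * zy + zy**2) / (1 - rho**2)
        nll += 0.5 * np.sum(q) + x.size * (
            np.log(2 * np.pi) + lsx + lsy + 0.5 * np.log1p(-(rho**2))
        )
    return nll


def _fit(negll, theta0, data, constraints):
    res = optimize.minimize(
        negll,
        theta0,
        args=(data,),
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative
        raise RuntimeError(f"moderated correlation fit did not converge: {res.message}")
    return res


def moderated_correlation_fit(
    pc, coordinate, ea_group, *, group_moments: str = "shared"
) -> ModCorrFit:
    """Maximum-likelihood fit of the correlation trend rho_g = rho0 + g*rho1.

    Parameters
    ----------
    pc, coordinate
        Score and coordinate vectors (complete cases used).
    ea_group
        Integer group codes 0..3 (parental EA level minus one).
    group_moments
        ``"shared"`` (default): one mean/variance pair across groups, only
        the correlation varies — isolates the correlation trend and keeps
        the likelihood-ratio test on 1 df.  ``"free"``: per-group means and
        variances (in the unconstrained two-group limit the fitted rho_g
        equal the per-group sample correlations).

    The likelihood-ratio statistic compares against the rho1 = 0 null and
    is referred to chi-square with 1 df.  ``rho1_se`` is derived from the
    numerical observed information at the optimum.
    """
    pc = np.asarray(pc, dtype=float)
    coord = np.asarray(coordinate, dtype=float)
    groups = np.asarray(ea_group)
    if not (pc.shape == coord.shape == groups.shape):
        raise ValueError("pc, coordinate and ea_group must have equal length")
    mask = ~(np.isnan(pc) | np.isnan(coord))
    pc, coord, groups = pc[mask], coord[mask], groups[mask]
    if not np.issubdtype(groups.dtype, np.integer):
        if not np.all(groups == groups.astype(int)):
            raise ValueError("ea_group must be integer-coded")
        groups = groups.astype(int)
    if groups.min() < 0 or groups.max() > 3:
        raise ValueError("ea_group codes must lie in 0..3")
    data = _group_stats(pc, coord, groups)
    for g, (x, _) in data.items():
        if x.size < 10:
            raise ValueError(f"group {g} has fewer than 10 complete pairs")
    glist = sorted(data)

    # starting values from sample moments
    r_g = {
        g: np.corrcoef(x, y)[0, 1] if np.std(x) > 0 and np.std(y) > 0 else 0.0
        for g, (x, y) in data.items()
    }
    gs = np.array(glist, dtype=float)
    rs = np.array([r_g[g] for g in glist])
    if glist == [0] or len(glist) == 1:
        raise ValueError("need at least two groups")
    slope, intercept = np.polyfit(gs, rs, 1)

    def trend_constraints(idx0, idx1):
        cons = []
        for g in glist:
            cons.append(
                {
                    "type": "ineq",
                    "fun": (lambda t, g=g: _RHO_BOUND - 1e-3 - (t[idx0] + g * t[idx1])),
                }
            )
            cons.append(
                {
                    "type": "ineq",
                    "fun": (lambda t, g=g: (t[idx0] + g * t[idx1]) + _RHO_BOUND - 1e-3),
                }
            )
        return cons

    if group_moments == "shared":
        negll = _bvn_negll_shared
        base = [
            pc.mean(),
            coord.mean(),
            np.log(pc.std() + 1e-12),
            np.log(coord.std() + 1e-12),
        ]
        idx0, idx1 = 4, 5
        theta_null = np.array(base + [np.clip(np.mean(rs), -0.99, 0.99), 0.0])
        nparams = 6
    elif group_moments == "free":
        negll = _bvn_negll_free
        base = []
        for g in glist:
            x, y = data[g]
            base += [x.mean(), y.mean(), np.log(x.std() + 1e-12), np.log(y.std() + 1e-12)]
        idx0, idx1 = len(base), len(base) + 1
        theta_null = np.array(base + [np.clip(np.mean(rs), -0.99, 0.99), 0.0])
        nparams = len(base) + 2
    else:
        raise ValueError("group_moments must be 'shared' or 'free'")

    cons = trend_constraints(idx0, idx1)

    # null: rho1 fixed at 0
    fix_rho1 = [{"type": "eq", "fun": lambda t: t[idx1]}]
    res_null = _fit(negll, theta_null, data, cons + fix_rho1)

    theta_full0 = res_null.x.copy()
    theta_full0[idx1] = np.clip(slope, -0.2, 0.2)
    theta_full0[idx0] = np.clip(intercept, -0.98, 0.98)
    res_full = _fit(negll, theta_full0, data, cons)
    if res_full.fun > res_null.fun:  # numerical: full can never be worse
        res_full = _fit(negll, res_null.x, data, cons)
        if res_full.fun > res_null.fun:
            res_full = res_null

    ll_full = -float(res_full.fun)
    ll_null = -float(res_null.fun)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    rho0 = float(res_full.x[idx0])
    rho1 = float(res_full.x[idx1])
    rho_by_group = {g: rho0 + g * rho1 for g in glist}
    at_bound = any(abs(r) > _RHO_BOUND - 2e-3 for r in rho_by_group.values())

    # observed-information SE for rho1 (numerical Hessian at the optimum)
    rho1_se = float("nan")
    try:
        h = _numerical_hessian(lambda t: negll(t, data), res_full.x)
        cov = np.linalg.inv(h)
        if cov[idx1, idx1] > 0:
            rho1_se = float(np.sqrt(cov[idx1, idx1]))
    except np.linalg.LinAlgError:
        pass

    return ModCorrFit(
        rho0=rho0,
        rho1=rho1,
        rho_by_group=rho_by_group,
        rho1_se=rho1_se,
        loglik_full=ll_full,
        loglik_null=ll_null,
        lrt_stat=lrt,
        p=float(stats.chi2.sf(lrt, df=1)),
        df=1,
        at_bound=at_bound,
        n_by_group={g: data[g][0].size for g in glist},
    )


def _numerical_hessian(f, x0, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for smooth likelihoods."""
    k = x0.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    return H
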