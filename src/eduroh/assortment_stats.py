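"""Spouse-EA contingency analysis and migration-distance group tests.

Covers the classic descriptives of educational assortment: the r x c
chi-square test of independence on the spouse educational-attainment
crosstab, Spearman's rank correlation with midranks for ties, a one-way
ANOVA of birthplace distance across EA levels, and post-hoc t-tests
between consecutive levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrosstabResult",
    "SpearmanResult",
    "AnovaResult",
    "ConsecutivePair",
    "contingency_chi2",
    "spearman_midrank",
    "spearman_from_table",
    "anova_by_level",
    "consecutive_level_ttests",
]


@dataclass
class CrosstabResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    spearman_rho: float
    n: int
    diagonal_share: float | None  # fraction of pairs on the diagonal (square tables)


class SpearmanResult(NamedTuple):
    rho: float
    p: float


@dataclass
class AnovaResult:
    f_stat: float
    p: float
    levels: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray


class ConsecutivePair(NamedTuple):
    levels: tuple
    t: float
    p: float


def contingency_chi2(observed) -> CrosstabResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts are the usual outer product of margins over the total;
    for square tables the diagonal share (fraction of concordant pairs) is
    reported, mirroring the way spousal trait tables are summarised.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("observed must be at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row/column margin in the contingency table")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    n = int(obs.sum())
    rho = spearman_from_table(obs).rho
    diag = float(np.trace(obs) / n) if obs.shape[0] == obs.shape[1] else None
    return CrosstabResult(
        observed=obs.astype(np.int64),
        expected=expected,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        spearman_rho=rho,
        n=n,
        diagonal_share=diag,
    )


def _spearman_p(rho: float, n: int, exact_max_n: int = 12) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_midrank(x, y, *, exact: bool = False) -> SpearmanResult:
    """Spearman's rho as the Pearson correlation of midranks.

    Ties get average (mid) ranks.  The p-value uses the t approximation;
    ``exact=True`` enumerates all permutations (only feasible for n <= 12).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if exact:
        if n > 12:
            raise ValueError("exact permutation p only supported for n <= 12")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return SpearmanResult(rho, count / total)
    return SpearmanResult(rho, _spearman_p(rho, n))


def spearman_from_table(table) -> SpearmanResult:
    """Spearman's rho of a weighted contingency table (no expansion needed).

    Equivalent to expanding the table to its n pairs and calling
    :func:`spearman_midrank`: midranks depend only on the margins, so the
    Pearson correlation is computed with cell counts as weights.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("table must be 2-D")
    n = tab.sum()
    if n <= 0:
        raise ValueError("empty table")
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    # midrank of category k = (count below) + (count_k + 1)/2
    mr_row = np.concatenate([[0.0], np.cumsum(row)])[:-1] + (row + 1) / 2.0
    mr_col = np.concatenate([[0.0], np.cumsum(col)])[:-1] + (col + 1) / 2.0
    mx = float(row @ mr_row) / n
    my = float(col @ mr_col) / n
    sx = np.sqrt(float(row @ (mr_row - mx) ** 2) / n)
    sy = np.sqrt(float(col @ (mr_col - my) ** 2) / n)
    if sx == 0 or sy == 0:
        raise ValueError("Spearman correlation undefined: constant margin")
    cov = float(((mr_row - mx)[:, None] * (mr_col - my)[None, :] * tab).sum()) / n
    rho = cov / (sx * sy)
    return SpearmanResult(float(rho), _spearman_p(rho, int(n)))


def anova_by_level(values, levels) -> AnovaResult:
    """One-way ANOVA of ``values`` across ordinal ``levels``.

    Groups with fewer than two observations are excluded with a warning;
    fewer than two usable groups is an error.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    uniq = np.unique(levels)
    groups, used = [], []
    for lev in uniq:
        g = values[levels == lev]
        g = g[~np.isnan(g)]
        if g.size < 2:
            warnings.warn(f"level {lev!r} has fewer than 2 observations; excluded")
            continue
        groups.append(g)
        used.append(lev)
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2 for ANOVA")
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(
        f_stat=float(f_stat),
        p=float(p),
        levels=np.asarray(used),
        means=np.array([g.mean() for g in groups]),
        sds=np.array([g.std(ddof=1) for g in groups]),
        ns=np.array([g.size for g in groups]),
    )


def consecutive_level_ttests(values, levels, *, equal_var: bool = True) -> list:
    """Two-sample t-tests between each pair of consecutive levels.

    Pooled-variance by default (the classic post-hoc output); Welch via
    ``equal_var=False``.  Pairs with an empty side are skipped with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    uniq = np.sort(np.unique(levels))
    out = []
    for lo, hi in zip(uniq, uniq[1:]):
        a = values[levels == lo]
        b = values[levels == hi]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            warnings.warn(f"levels ({lo!r}, {hi!r}) lack data; pair skipped")
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out.append(ConsecutivePair(levels=(lo, hi), t=float(t), p=float(p)))
    return out
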