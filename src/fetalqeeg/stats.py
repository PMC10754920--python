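"""Nonparametric statistical stage.

Three procedures, exactly as the analysis plan prescribes: a Friedman
repeated-measures test across phases (complete-case rows, mid-rank ties,
tie-corrected chi-square approximation), pairwise Wilcoxon signed-rank
post-hoc comparisons (zero differences dropped, exact 2^n sign-pattern null
for up to 15 informative pairs, normal approximation with tie correction
above), and Spearman rank correlations (exact permutation null for n <= 8,
t approximation above).  No multiple-testing correction is applied by
default — the original analysis applied none — but Holm adjustment of the
post-hoc p-values is available behind a flag.

The Friedman statistic uses the rank-ANOVA form

    Q = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4),

which reduces to the classical 12/(nk(k+1)) formula without ties and remains
well defined with them; a grid in which every row is fully tied has no rank
variation and is reported as statistic 0, p = 1 (degenerate), rather than the
0/0 a naive implementation produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

WILCOXON_EXACT_MAX_N = 15
SPEARMAN_EXACT_MAX_N = 8


class InsufficientDataError(ValueError):
    """Too few complete observations for the requested test."""


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_used: int
    degenerate: bool = False
    labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def _complete_rows(grid: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(grid, dtype=float)
    return arr[np.all(np.isfinite(arr), axis=1)]


def friedman(grid: pd.DataFrame | np.ndarray) -> TestResult:
    """Friedman chi-square over a subjects x conditions grid.

    Rows with any missing cell are dropped (a subject lost to the stop rule
    cannot contribute a complete row); ``n_used`` reports the rows kept.
    """
    data = _complete_rows(grid)
    n, k = data.shape if data.ndim == 2 else (0, 0)
    if n < 2:
        raise InsufficientDataError("Friedman test needs >= 2 complete subjects")
    if k < 3:
        raise InsufficientDataError("Friedman test needs >= 3 conditions")
    ranks = sps.rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        return TestResult("friedman", 0.0, 1.0, n, degenerate=True)
    q = float(numer / denom)
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult("friedman", q, p, n)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p from full enumeration of the 2^n sign patterns."""
    n = len(ranks)
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    dist = signs @ ranks
    p_low = np.mean(dist <= w_plus + 1e-9)
    p_high = np.mean(dist >= w_plus - 1e-9)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _wilcoxon_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    # tie-corrected variance: sum of squared ranks / 4
    sigma2 = float(np.sum(ranks**2)) / 4.0
    if sigma2 == 0:
        return 1.0
    z = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / np.sqrt(sigma2)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; |differences| are mid-ranked.  All-zero
    differences are a degenerate no-signal outcome flagged with p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon", np.nan, 1.0, 0, degenerate=True, labels=labels)
    w_plus, ranks = _signed_rank_statistic(d)
    if n <= WILCOXON_EXACT_MAX_N:
        p = _wilcoxon_exact_p(ranks, w_plus)
        method = "wilcoxon-exact"
    else:
        p = _wilcoxon_normal_p(ranks, w_plus)
        method = "wilcoxon-approx"
    return TestResult(method, w_plus, p, n, labels=labels)


def wilcoxon_posthoc(
    grid: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    holm: bool = False,
) -> list[TestResult]:
    """Pairwise signed-rank comparisons of the grid's conditions.

    Each pair uses its own pairwise-complete rows.  ``holm`` optionally
    applies Holm step-down adjustment across the reported pairs (off by
    default: the original analysis applied no correction).
    """
    conditions = list(grid.columns)
    if pairs is None:
        pairs = list(combinations(conditions, 2))
    results = []
    for a, b in pairs:
        sub = grid[[a, b]].dropna()
        results.append(wilcoxon(sub[a].to_numpy(), sub[b].to_numpy(), labels=(a, b)))
    if holm:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        adjusted = {}
        running = 0.0
        for rank_idx, idx in enumerate(order):
            running = max(running, (m - rank_idx) * results[idx].p_value)
            adjusted[idx] = min(1.0, running)
        results = [
            TestResult(r.method + "+holm", r.statistic, adjusted[i], r.n_used, r.degenerate, r.labels)
            for i, r in enumerate(results)
        ]
    return results


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Permutation null over all n! orderings (mid-ranks preserved)."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman rank correlation with missing pairs dropped.

    rho is the product-moment correlation of mid-ranks; the two-sided p-value
    is exact (all-permutations) for n <= 8 and the t approximation above.
    Zero rank variance in either argument is an undefined correlation, never
    a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Spearman needs >= 3 complete pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(labels[0], labels[1], np.nan, np.nan, n, degenerate=True)
    rho, p_t = sps.spearmanr(x, y)
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rx, ry, float(rho))
    else:
        p = float(p_t)
    return CorrelationResult(labels[0], labels[1], float(rho), p, n)


def correlation_table(
    observations: pd.DataFrame,
    row_markers: Sequence[str],
    col_markers: Sequence[str],
    min_n: int = 3,
) -> pd.DataFrame:
    """Grid of Spearman correlations over pooled subject-phase observations.

    Returns a long table (row_marker, col_marker, rho, p_value, n); cells
    with fewer than ``min_n`` complete pairs are marked missing.
    """
    rows = []
    for rm in row_markers:
        for cm in col_markers:
            record = {"qeeg": rm, "marker": cm, "rho": np.nan, "p_value": np.nan, "n": 0}
            if rm in observations and cm in observations:
                sub = observations[[rm, cm]].dropna()
                if len(sub) >= min_n:
                    res = spearman(sub[rm], sub[cm], labels=(rm, cm))
                    record.update(rho=res.rho, p_value=res.p_value, n=res.n)
            rows.append(record)
    return pd.DataFrame(rows)
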