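"""Elementary shared statistics: ranks, correlation tests, BH adjustment."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "MultipleTestResult",
    "average_ranks",
    "spearman",
    "pearson",
    "bh_adjust",
]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class MultipleTestResult:
    raw_p: np.ndarray
    q_values: np.ndarray
    rejected: np.ndarray
    alpha: float


def average_ranks(x) -> np.ndarray:
    """Ranks 1..n with ties assigned the mean of their covered ranks."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("cannot rank an empty vector")
    return sps.rankdata(x, method="average")


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input vector")
    return x, y


def _t_pvalue(rho: float, n: int) -> float:
    # two-sided p from t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df
    if abs(rho) >= 1.0:
        return float(np.finfo(float).tiny)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-approximation p-value."""
    x, y = _validate_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r, _t_pvalue(r, x.size), x.size)


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation: Pearson on average ranks.

    p-values use the two-sided t-approximation for all n; `exact=True`
    switches to the exact permutation distribution (only feasible for n <= 9).
    """
    x, y = _validate_pair(x, y)
    rx = average_ranks(x)
    ry = average_ranks(y)
    res = pearson(rx, ry)
    if exact:
        if x.size > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        res = CorrelationResult(res.rho, _exact_spearman_p(rx, ry, res.rho), res.n)
    return res


def _exact_spearman_p(rx, ry, rho) -> float:
    n = rx.size
    rxc = rx - rx.mean()
    denom = np.sqrt((rxc @ rxc) * ((ry - ry.mean()) @ (ry - ry.mean())))
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = (rxc @ (ry[list(perm)] - ry.mean())) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def bh_adjust(p, alpha: float = 0.05) -> MultipleTestResult:
    """Benjamini-Hochberg step-up adjustment at FDR level alpha.

    q_i = min over j >= i (in raw-p order) of m * p_(j) / j, capped at 1;
    a hypothesis is rejected iff its q-value is <= alpha (equivalent to the
    step-up rule rejecting ranks <= max{i : p_(i) <= i*alpha/m}).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q = np.empty(m)
    if m:
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        q[order] = np.minimum(q_sorted, 1.0)
    return MultipleTestResult(p, q, q <= alpha, alpha)
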