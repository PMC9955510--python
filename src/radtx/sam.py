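"""Significance Analysis of Microarrays (SAM), reimplemented.

Covers the two-class unpaired problem (moderated d = r / (s + s0) with the
fudge factor s0, permutation-based expected order statistics, delta
thresholding with permutation FDR estimation, and an optional fold-change
gate) and the quantitative variant that uses the Spearman rank correlation
coefficient of each gene with a continuous response as the statistic.

Conventions follow the reference SAM procedure: the null proportion pi0 is
estimated from the central quartiles of the permuted statistics and the FDR
at a threshold delta is pi0 times the median permutation count of statistics
beyond the cuts over the observed number of calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix

__all__ = [
    "SamTwoClassResult",
    "SamQuantResult",
    "compute_s0",
    "sam_two_class",
    "fold_change_filter",
    "sam_quantitative",
]

DELTA_GRID_SIZE = 200


# ---------------------------------------------------------------------------
# fudge factor


def compute_s0(r, s) -> float:
    """SAM fudge factor: the candidate (0 or a percentile of s) that minimizes
    the coefficient of variation of window-wise MADs of d = r / (s + s0).

    Genes are windowed by quantiles of s; the returned s0 stabilizes the
    spread of d across the variance range.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("r and s must be 1-D vectors of equal length")
    if r.size < 10:
        raise ValueError("s0 estimation requires at least 10 genes")
    if np.ptp(s) == 0:
        return 0.0

    candidates = np.unique(np.concatenate(([0.0], np.percentile(s, np.arange(0, 101, 5)))))
    n_windows = int(min(100, max(2, r.size // 10)))
    edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)

    best_cv = np.inf
    best = 0.0
    order = np.argsort(window, kind="stable")
    w_sorted = window[order]
    bounds = np.searchsorted(w_sorted, np.arange(n_windows + 1))
    for alpha in candidates:
        d = r / (s + alpha)
        d_sorted = d[order]
        mads = []
        for w in range(n_windows):
            lo, hi = bounds[w], bounds[w + 1]
            if hi - lo < 2:
                continue
            seg = d_sorted[lo:hi]
            mads.append(np.median(np.abs(seg - np.median(seg))))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best_cv = cv
            best = float(alpha)
    return best


# ---------------------------------------------------------------------------
# shared delta/FDR machinery


@dataclass
class _DeltaAnalysis:
    dbar: np.ndarray
    delta: float
    fdr_table: pd.DataFrame
    cuthi: float
    cutlo: float
    fdr_achieved: float
    pi0: float


def _estimate_pi0(d: np.ndarray, perm: np.ndarray) -> float:
    q25, q75 = np.percentile(perm, [25.0, 75.0])
    inside = np.count_nonzero((d > q25) & (d < q75))
    return float(min(1.0, inside / (0.5 * d.size)))


def _counts_beyond(perm: np.ndarray, cuthi: np.ndarray, cutlo: np.ndarray) -> np.ndarray:
    """Per-permutation counts of statistics >= cuthi or <= cutlo.

    perm is genes x permutations; cuthi/cutlo are per-delta cut values with
    sentinels (above max / below min) meaning 'no cut'. Returns deltas x perms.
    """
    g, p = perm.shape
    lo = perm.min() - 1.0
    hi = perm.max() + 1.0
    span = (hi - lo) * 2.0
    offsets = np.arange(p) * span
    flat = np.sort(perm, axis=0).T.reshape(-1) + np.repeat(offsets, g)
    qhi = np.clip(cuthi, lo, hi)[:, None] + offsets[None, :]
    qlo = np.clip(cutlo, lo, hi)[:, None] + offsets[None, :]
    idx_hi = np.searchsorted(flat, qhi.reshape(-1), side="left").reshape(qhi.shape)
    idx_lo = np.searchsorted(flat, qlo.reshape(-1), side="right").reshape(qlo.shape)
    blocks = (np.arange(p) + 1) * g
    count_hi = blocks[None, :] - idx_hi
    count_lo = idx_lo - (blocks[None, :] - g)
    return count_hi + count_lo


def _delta_analysis(
    d: np.ndarray,
    perm: np.ndarray,
    fdr_target: float,
    delta_override: float | None,
    pi0: float | None,
) -> _DeltaAnalysis:
    g = d.size
    order = np.argsort(d, kind="stable")  # ties broken by original index
    d_sorted = d[order]
    dbar = np.sort(perm, axis=0).mean(axis=1)
    diff = d_sorted - dbar
    if pi0 is None:
        pi0 = _estimate_pi0(d, perm)

    max_dev = float(np.max(np.abs(diff))) if g else 0.0
    grid = np.linspace(0.0, max_dev, DELTA_GRID_SIZE)
    if delta_override is not None and delta_override not in grid:
        grid = np.sort(np.append(grid, delta_override))

    lo_sent = perm.min() - 1.0
    hi_sent = perm.max() + 1.0

    # cuthi: scanning upward from the first index where d_(i) >= dbar_(i),
    # the smallest d_(i) with d_(i) - dbar_(i) >= delta. cutlo symmetric.
    up = diff.copy()
    nonneg = np.nonzero(diff >= 0)[0]
    if nonneg.size:
        up[: nonneg[0]] = -np.inf
    else:
        up[:] = -np.inf
    hits_up = up[None, :] >= grid[:, None]
    idx_up = hits_up.argmax(axis=1)
    has_up = hits_up.any(axis=1)
    cuthi = np.where(has_up, d_sorted[idx_up], hi_sent)

    down = diff.copy()
    nonpos = np.nonzero(diff <= 0)[0]
    if nonpos.size:
        down[nonpos[-1] + 1 :] = np.inf
    else:
        down[:] = np.inf
    hits_dn = (down[None, ::-1] <= -grid[:, None])
    idx_dn = hits_dn.argmax(axis=1)
    has_dn = hits_dn.any(axis=1)
    cutlo = np.where(has_dn, d_sorted[::-1][idx_dn], lo_sent)

    n_pos = g - np.searchsorted(d_sorted, np.minimum(cuthi, hi_sent), side="left")
    n_pos = np.where(has_up, n_pos, 0)
    n_neg = np.searchsorted(d_sorted, np.maximum(cutlo, lo_sent), side="right")
    n_neg = np.where(has_dn, n_neg, 0)
    n_called = n_pos + n_neg

    med_counts = np.median(_counts_beyond(perm, cuthi, cutlo), axis=1)
    fdr = pi0 * med_counts / np.maximum(1, n_called)

    table = pd.DataFrame(
        {"delta": grid, "n_called": n_called, "fdr": np.minimum(fdr, 1.0)}
    )

    if delta_override is not None:
        j = int(np.argmin(np.abs(grid - delta_override)))
        delta = float(grid[j])
    else:
        ok = np.nonzero(fdr <= fdr_target)[0]
        if ok.size == 0:
            return _DeltaAnalysis(dbar, np.inf, table, hi_sent, lo_sent, np.inf, pi0)
        j = int(ok[0])
        delta = float(grid[j])
    return _DeltaAnalysis(
        dbar, delta, table, float(cuthi[j]), float(cutlo[j]), float(min(fdr[j], 1.0)), pi0
    )


# ---------------------------------------------------------------------------
# two-class unpaired SAM


@dataclass
class SamTwoClassResult:
    gene_ids: list[str]
    d: np.ndarray
    r: np.ndarray
    s: np.ndarray
    s0: float
    dbar: np.ndarray
    delta: float
    fdr_table: pd.DataFrame
    called_positive: list[str]
    called_negative: list[str]
    pi0: float
    n_perm: int
    fdr_achieved: float = np.nan
    cuthi: float = np.nan
    cutlo: float = np.nan

    @property
    def called(self) -> list[str]:
        return self.called_positive + self.called_negative


def _resolve_labels(expr: ExpressionMatrix, labels) -> np.ndarray:
    if labels is None:
        labels = expr.sample_class
    labels = np.asarray([str(l) for l in labels])
    if labels.size != expr.n_samples:
        raise ValueError("label vector length does not match sample count")
    return labels


def _pooled_stats(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """Numerator (group1 mean - group2 mean) and pooled-SE denominator."""
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    m1 = values[:, mask1].mean(axis=1)
    m2 = values[:, mask2].mean(axis=1)
    ss1 = ((values[:, mask1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((values[:, mask2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return m1 - m2, s


def sam_two_class(
    expr: ExpressionMatrix,
    labels=None,
    n_perm: int = 1000,
    fdr_target: float = 0.05,
    delta_override: float | None = None,
    fold_change: float | None = None,
    seed: int = 0,
    s0: float | None = None,
    pi0: float | None = None,
) -> SamTwoClassResult:
    """Two-class unpaired SAM, cancer minus normal.

    Permutations shuffle the class labels; the expected order statistics
    dbar_(i) are the mean over permutations of the i-th order statistic of the
    permuted d. If `delta_override` is None the threshold is the smallest grid
    value whose estimated FDR is <= `fdr_target` (empty call set if
    unreachable). A `fold_change` gate additionally requires
    |mean difference| >= log2(fold_change) on the input (log2-scale) values.
    `s0=None` estimates the fudge factor from the data; `pi0=None` estimates
    the null proportion from the permuted statistics (pass 1.0 for the
    original Tusher convention).
    """
    labels = _resolve_labels(expr, labels)
    mask_c = labels == "cancer"
    mask_n = labels == "normal"
    if mask_c.sum() < 2 or mask_n.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    values = expr.values[:, mask_c | mask_n]
    sub_labels = labels[mask_c | mask_n]
    is_c = sub_labels == "cancer"
    n = values.shape[1]
    n1 = int(is_c.sum())

    r, s = _pooled_stats(values, is_c, ~is_c)
    if s0 is None:
        s0 = compute_s0(r, s)
    d = r / (s + s0)

    # permuted statistics: shuffle class labels, recompute d with the same s0
    rng = np.random.default_rng(seed)
    g = values.shape[0]
    vsq = values**2
    tot = values.sum(axis=1)
    tot2 = vsq.sum(axis=1)
    perm = np.empty((g, n_perm))
    n2 = n - n1
    for p in range(n_perm):
        idx = rng.permutation(n)[:n1]
        z = np.zeros(n)
        z[idx] = 1.0
        s1 = values @ z
        s1sq = vsq @ z
        rp = s1 / n1 - (tot - s1) / n2
        ss = (s1sq - s1**2 / n1) + (tot2 - s1sq - (tot - s1) ** 2 / n2)
        sp = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n - 2))
        perm[:, p] = rp / (sp + s0)

    ana = _delta_analysis(d, perm, fdr_target, delta_override, pi0)

    pos = d >= ana.cuthi
    neg = d <= ana.cutlo
    if fold_change is not None:
        if fold_change < 1:
            raise ValueError("fold_change threshold must be >= 1")
        gate = np.abs(r) >= np.log2(fold_change)
        pos &= gate & (r > 0)
        neg &= gate & (r < 0)
    gid = np.asarray(expr.gene_ids)
    return SamTwoClassResult(
        gene_ids=list(expr.gene_ids),
        d=d,
        r=r,
        s=s,
        s0=float(s0),
        dbar=ana.dbar,
        delta=ana.delta,
        fdr_table=ana.fdr_table,
        called_positive=list(gid[pos]),
        called_negative=list(gid[neg]),
        pi0=ana.pi0,
        n_perm=n_perm,
        fdr_achieved=ana.fdr_achieved,
        cuthi=ana.cuthi,
        cutlo=ana.cutlo,
    )


def fold_change_filter(
    expr: ExpressionMatrix, labels=None, threshold: float = 2.0
) -> dict[str, int]:
    """Genes whose |log2 cancer mean - log2 normal mean| >= log2(threshold).

    Returns gene -> sign (+1 if higher in cancer, -1 if higher in normal).
    """
    if threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    labels = _resolve_labels(expr, labels)
    mask_c = labels == "cancer"
    mask_n = labels == "normal"
    if not mask_c.any() or not mask_n.any():
        raise ValueError("both classes must be non-empty")
    diff = expr.values[:, mask_c].mean(axis=1) - expr.values[:, mask_n].mean(axis=1)
    passing = np.abs(diff) >= np.log2(threshold)
    return {
        g: (1 if diff[i] > 0 else -1)
        for i, g in enumerate(expr.gene_ids)
        if passing[i]
    }


# ---------------------------------------------------------------------------
# quantitative SAM (Spearman statistic)


@dataclass
class SamQuantResult:
    gene_ids: list[str]
    stat: np.ndarray
    dbar: np.ndarray
    delta: float
    called: list[str]
    fdr_achieved: float
    fdr_table: pd.DataFrame
    n_perm: int
    pi0: float
    perm_stats: np.ndarray | None = field(default=None, repr=False)


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks scaled to zero mean, unit (population) SD."""
    ranks = sps.rankdata(values, method="average", axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1)
    sd[sd == 0] = 1.0  # constant rows get statistic 0
    return ranks / sd[:, None]


def sam_quantitative(
    expr: ExpressionMatrix,
    response,
    n_perm: int = 1000,
    fdr_target: float = 0.05,
    seed: int = 0,
    delta_override: float | None = None,
    pi0: float | None = None,
    keep_perm_stats: bool = False,
) -> SamQuantResult:
    """SAM for a quantitative response with the Spearman rho statistic.

    Gene vectors and the response are rank-transformed and SD-scaled so the
    per-gene statistic is exactly the Spearman rank correlation with the
    response (s0 = 0; the statistic is already scale-free). Permutations
    shuffle the response across samples.
    """
    response = np.asarray(response, dtype=float)
    if response.size != expr.n_samples:
        raise ValueError("response length does not match sample count")
    if response.size < 4:
        raise ValueError("quantitative SAM requires n >= 4 samples")
    if np.ptp(response) == 0:
        raise ValueError("undefined correlation: constant response")

    n = response.size
    z_genes = _rank_standardize(expr.values)
    z_resp = _rank_standardize(response[None, :])[0]
    stat = z_genes @ z_resp / n

    rng = np.random.default_rng(seed)
    perm_resp = np.empty((n, n_perm))
    for p in range(n_perm):
        perm_resp[:, p] = z_resp[rng.permutation(n)]
    perm = z_genes @ perm_resp / n

    ana = _delta_analysis(stat, perm, fdr_target, delta_override, pi0)
    called_mask = (stat >= ana.cuthi) | (stat <= ana.cutlo)
    gid = np.asarray(expr.gene_ids)
    return SamQuantResult(
        gene_ids=list(expr.gene_ids),
        stat=stat,
        dbar=ana.dbar,
        delta=ana.delta,
        called=list(gid[called_mask]),
        fdr_achieved=ana.fdr_achieved,
        fdr_table=ana.fdr_table,
        n_perm=n_perm,
        pi0=ana.pi0,
        perm_stats=perm if keep_perm_stats else None,
    )
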