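"""Rank statistics for response prediction: AUC, bootstrap CIs,
Mann–Whitney U.

The AUC is the rank-based (Mann–Whitney) statistic with ties counted
one half — the probability that a random responder's score outranks a
random non-responder's. Confidence intervals are stratified percentile
bootstraps over patients. The Mann–Whitney test uses exact enumeration
of the permutation null for small samples (n_x + n_y <= 16) and the
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = ["auc", "roc_points", "bootstrap_ci", "mannwhitney_u"]

EXACT_MW_LIMIT = 16


def auc(scores, labels) -> float:
    """Rank-based AUC of `scores` against boolean `labels` (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> list:
    """(FPR, TPR) pairs over all score thresholds, monotone in FPR."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    # collapse ties: keep the last point of each distinct threshold
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = tps[distinct] / max(labels.sum(), 1)
    fpr = fps[distinct] / max((~labels).sum(), 1)
    return [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))


def bootstrap_ci(scores, labels, n_boot: int = 2000,
                 seed: int = 0, alpha: float = 0.05) -> tuple:
    """Stratified percentile bootstrap CI for the AUC.

    Resamples patients within each class (so every resample keeps both
    classes); returns the (alpha/2, 1-alpha/2) percentile interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap CI needs both classes present")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        vals[b] = auc(np.r_[ps, ns],
                      np.r_[np.ones(len(ps), bool), np.zeros(len(ns), bool)])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x > y) pairs + half the ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mannwhitney_u(x, y) -> tuple:
    """Two-sided Mann–Whitney U test; returns (U_x, p).

    Exact permutation null (enumeration over group assignments of the
    pooled values, ties included) when n_x + n_y <= 16; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    n, m = len(x), len(y)
    if n + m <= EXACT_MW_LIMIT:
        pooled = np.concatenate([x, y])
        total = comb(n + m, n)
        mid = n * m / 2.0
        dev = abs(u - mid)
        extreme = 0
        idx = np.arange(n + m)
        for c in combinations(idx, n):
            sel = np.zeros(n + m, bool)
            sel[list(c)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            if abs(u_perm - mid) >= dev - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  use_continuity=True, method="asymptotic")
        p = float(p)
    return u, min(p, 1.0)
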