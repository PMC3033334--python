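"""Exact Wilcoxon signed-rank tests for small probe sets.

Per-gene change calls compare the ~11 probe intensities of one sample
against the matched probes of another, so the relevant null distributions
live at very small n where the normal approximation is poor.  This module
computes the exact distribution of the positive-rank sum W+ by dynamic
programming, including the tied-rank case: |differences| that tie receive
the average of their ranks, which is a multiple of 1/2, so doubling every
rank keeps the DP on an integer lattice.

Conventions (fixed for the whole package):

* zero differences are dropped before ranking (Wilcoxon's original rule);
* an empty difference vector yields p = 1 for every alternative;
* two-sided p = min(1, 2 * min(P(W+ <= w), P(W+ >= w)));
* exact distributions are used for n <= EXACT_LIMIT effective differences,
  a normal approximation with tie correction and continuity correction
  above that.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as _sps

EXACT_LIMIT = 25


def _average_ranks(sorted_abs: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) of an already-sorted |difference| vector."""
    n = sorted_abs.size
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


@lru_cache(maxsize=512)
def _wplus_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of sign assignments per value of 2*W+.

    doubled_ranks are the tied-averaged ranks times two (integers).  The
    returned array c has c[s] = number of the 2^n sign vectors whose
    positive doubled-rank sum equals s; it sums to 2^n.
    """
    total = sum(doubled_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def _exact_pvalues(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """(P(W+ <= w), P(W+ >= w)) from the exact null distribution."""
    doubled = tuple(int(round(2 * r)) for r in np.sort(ranks))
    counts = _wplus_counts(doubled)
    denom = counts.sum()
    s = int(round(2 * w_plus))
    p_le = counts[: s + 1].sum() / denom
    p_ge = counts[s:].sum() / denom
    return p_le, p_ge


def _normal_pvalues(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    n = ranks.size
    mu = n * (n + 1) / 4.0
    # variance with tie correction expressed through the realized ranks
    var = float(np.sum(ranks**2)) / 4.0
    sd = np.sqrt(var)
    p_le = _sps.norm.cdf((w_plus - mu + 0.5) / sd)
    p_ge = _sps.norm.sf((w_plus - mu - 0.5) / sd)
    return float(p_le), float(p_ge)


def signed_rank_test(diffs: np.ndarray, alternative: str = "two-sided") -> float:
    """P-value of the Wilcoxon signed-rank test on a difference vector.

    alternative: "two-sided", "greater" (median difference > 0) or "less".
    Zero differences are dropped; if none remain, returns 1.0.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks_sorted = _average_ranks(absd[order])
    signs_sorted = d[order] > 0
    w_plus = float(ranks_sorted[signs_sorted].sum())
    if d.size <= EXACT_LIMIT:
        p_le, p_ge = _exact_pvalues(ranks_sorted, w_plus)
    else:
        p_le, p_ge = _normal_pvalues(ranks_sorted, w_plus)
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Unmatched Mann-Whitney rank-sum variant (exact where scipy affords it)."""
    res = _sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# vectorised helper for the bulk caller


def signed_rank_pvalues(diffs: np.ndarray, alternative: str = "two-sided") -> np.ndarray:
    """Row-wise signed-rank p-values for a (n_rows, n_diffs) array.

    Rows free of zeros and ties share the cached untied null distribution,
    so the common case is a single vectorised rank computation plus a table
    lookup; degenerate rows fall back to the general scalar routine.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2:
        raise ValueError("diffs must be 2-d")
    n_rows, n = d.shape
    out = np.empty(n_rows, dtype=float)
    absd = np.abs(d)
    has_zero = (d == 0.0).any(axis=1)
    srt = np.sort(absd, axis=1)
    has_tie = (np.diff(srt, axis=1) == 0.0).any(axis=1)
    clean = ~(has_zero | has_tie)
    if clean.any() and n <= EXACT_LIMIT:
        ranks = _sps.rankdata(absd[clean], axis=1)
        w_plus = np.where(d[clean] > 0, ranks, 0.0).sum(axis=1)
        counts = _wplus_counts(tuple(range(2, 2 * n + 1, 2)))
        cdf = np.cumsum(counts)
        denom = cdf[-1]
        s = np.rint(2 * w_plus).astype(int)
        p_le = cdf[s] / denom
        p_ge = (denom - np.concatenate(([0.0], cdf))[s]) / denom
        if alternative == "greater":
            out[clean] = np.minimum(1.0, p_ge)
        elif alternative == "less":
            out[clean] = np.minimum(1.0, p_le)
        else:
            out[clean] = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    else:
        clean = np.zeros(n_rows, dtype=bool)
    for i in np.nonzero(~clean)[0]:
        out[i] = signed_rank_test(d[i], alternative)
    return out
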