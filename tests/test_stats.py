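"""Exactness of the signed-rank machinery against brute-force enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon

from stageset.stats import signed_rank_pvalues, signed_rank_test


def enum_signed_rank(diffs: np.ndarray, alternative: str) -> float:
    """Independent oracle: enumerate all 2^n sign assignments.

    Computes W+ for the observed data with tied-average ranks, then the
    exact tail probabilities over every equally likely sign vector of the
    same |differences|.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    absd = np.abs(d)
    # tied-average ranks
    order = np.argsort(absd)
    ranks = np.empty(d.size)
    sa = absd[order]
    i = 0
    while i < d.size:
        j = i
        while j + 1 < d.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=d.size):
        w = ranks[np.array(signs, bool)].sum()
        total += 1
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    p_le, p_ge = n_le / total, n_ge / total
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
def test_signed_rank_matches_enumeration(alternative, rng):
    """Exact agreement with sign-assignment enumeration up to n = 12,
    including ties and zero differences."""
    for _ in range(60):
        n = int(rng.integers(1, 13))
        d = rng.normal(size=n)
        style = rng.integers(0, 3)
        if style == 1:  # force ties in |d|
            d = np.round(d, 0)
        elif style == 2:  # force zeros
            d[rng.integers(0, n)] = 0.0
        p = signed_rank_test(d, alternative)
        p_enum = enum_signed_rank(d, alternative)
        assert p == pytest.approx(p_enum, abs=1e-12)


def test_signed_rank_matches_scipy_on_tie_free_data(rng):
    """On tie-free data the p-values equal scipy's exact Wilcoxon."""
    for _ in range(100):
        n = int(rng.integers(4, 13))
        d = rng.normal(size=n)
        if len(set(np.abs(d))) < n:
            continue
        for alt in ("two-sided", "greater", "less"):
            assert signed_rank_test(d, alt) == pytest.approx(
                wilcoxon(d, alternative=alt, method="exact").pvalue, abs=1e-12
            )


def test_vectorised_path_equals_scalar(rng):
    """The bulk row-wise routine and the scalar routine agree, on both the
    clean fast path and tied/zero fallback rows."""
    d = rng.normal(size=(50, 11))
    d[3] = np.round(d[3], 0)
    d[7, 2] = 0.0
    for alt in ("two-sided", "greater", "less"):
        bulk = signed_rank_pvalues(d, alt)
        scalar = np.array([signed_rank_test(row, alt) for row in d])
        np.testing.assert_allclose(bulk, scalar, atol=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 1)),
        min_size=1,
        max_size=10,
    )
)
def test_signed_rank_is_a_valid_pvalue(d):
    """p in (0, 1]; degenerate all-zero vectors give exactly 1."""
    arr = np.asarray(d)
    for alt in ("two-sided", "greater", "less"):
        p = signed_rank_test(arr, alt)
        assert 0.0 < p <= 1.0
        if (arr == 0).all():
            assert p == 1.0


def test_large_n_normal_approximation_close_to_exact(rng):
    """Just above the exact-computation limit the normal approximation with
    continuity correction stays within a percent of the enumerable truth at
    moderate tail depth."""
    d = rng.normal(0.4, 1.0, size=30)
    p_norm = signed_rank_test(d, "two-sided")
    p_scipy = wilcoxon(d, alternative="two-sided", method="approx", correction=True).pvalue
    assert p_norm == pytest.approx(p_scipy, rel=0.05)
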