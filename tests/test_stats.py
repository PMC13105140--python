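"""Unit and oracle tests for the shared statistical machinery.

Exact rank-test p-values are checked against independent brute-force
enumeration (all rank splits for the rank-sum test, all sign patterns for
the signed-rank test); BH against hand-computed step-up values; effect
sizes against direct pair counting.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from precvax.stats import (
    CorrelationResult,
    DegenerateDataError,
    assay_ratio_compare,
    bh_adjust,
    paired_t,
    rank_biserial_paired,
    rank_biserial_unpaired,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ------------------------------------------------------- brute-force oracles


def brute_ranksum_p(x, y):
    """Two-sided exact p by enumerating all C(n1+n2, n1) rank splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = float(np.sum(ranks[list(combo)])) - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_signedrank_p(d):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


# ----------------------------------------------------------------- rank-sum


def test_ranksum_minimal_exact_case():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1 / 3)
    assert res.effect_r == -1.0


def test_ranksum_identical_samples_p_one():
    res = wilcoxon_rank_sum([1.0, 2.5, 3.5], [4.5, 0.5, 2.0])
    # same-size untied samples with interleaved values: p well above 0.05
    assert res.p > 0.5


def test_ranksum_symmetry_same_multiset():
    x = [1.0, 2.0, 3.0]
    res = wilcoxon_rank_sum(x, [1.5, 2.5, 0.5])
    flipped = wilcoxon_rank_sum([1.5, 2.5, 0.5], x)
    assert res.p == pytest.approx(flipped.p)
    assert res.effect_r == pytest.approx(-flipped.effect_r)


@pytest.mark.parametrize("n1,n2,seed", [(3, 5, 0), (4, 4, 1), (6, 7, 2), (7, 9, 3), (2, 10, 4)])
def test_ranksum_exact_matches_enumeration(n1, n2, seed):
    rng = np.random.Generator(np.random.PCG64(seed))
    x = rng.normal(size=n1)
    y = rng.normal(0.5, size=n2)
    res = wilcoxon_rank_sum(x, y)
    assert "exact" in res.method
    assert res.p == pytest.approx(brute_ranksum_p(x, y), abs=1e-12)


def test_ranksum_exact_vs_approx_agreement():
    """Exact and normal-approximation p agree within 0.01 for n=8-10."""
    rng = np.random.Generator(np.random.PCG64(7))
    for _ in range(10):
        x = rng.normal(size=9)
        y = rng.normal(0.3, size=10)
        exact = wilcoxon_rank_sum(x, y, exact_max_n=10)
        approx = wilcoxon_rank_sum(x, y, exact_max_n=0)
        assert abs(exact.p - approx.p) < 0.01


def test_ranksum_type_i_error_calibrated():
    """Null rejection rate at alpha=0.05 stays within [0.035, 0.065]."""
    rng = np.random.Generator(np.random.PCG64(99))
    x = rng.normal(size=(1000, 50))
    y = rng.normal(size=(1000, 50))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1)
    rate = float(np.mean(res.pvalue < 0.05))
    assert 0.035 <= rate <= 0.065


def test_ranksum_empty_input_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


# --------------------------------------------------------------- signed-rank


def test_signedrank_all_positive_differences():
    res = wilcoxon_signed_rank([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
    assert res.p == pytest.approx(2 / 32)
    assert res.effect_r == 1.0


def test_signedrank_constant_shift_effect_r_one():
    pre = np.arange(10, dtype=float)
    res = wilcoxon_signed_rank(pre, pre + 3.0)
    assert res.effect_r == 1.0


@pytest.mark.parametrize("seed,n", [(0, 4), (1, 5), (2, 6), (3, 7), (4, 8)])
def test_signedrank_exact_matches_enumeration(seed, n):
    rng = np.random.Generator(np.random.PCG64(seed))
    d = rng.normal(0.4, 1.0, size=n)
    res = wilcoxon_signed_rank(np.zeros(n), d)
    assert "exact" in res.method
    assert res.p == pytest.approx(brute_signedrank_p(d), abs=1e-12)


def test_signedrank_mixed_signs_hand_case():
    d = [-1.0, 2.0, -3.0, 4.0]
    res = wilcoxon_signed_rank(np.zeros(4), d)
    assert res.statistic == 6.0  # W+ = rank(2)+rank(4) = 2+4
    assert res.p == pytest.approx(brute_signedrank_p(d), abs=1e-12)


def test_signedrank_zero_differences_dropped_and_all_zero_errors():
    res = wilcoxon_signed_rank([1, 1, 0, 0, 0], [1, 1, 1, 2, 3])
    assert res.n1 == 3
    assert any(f.startswith("zero_diffs_dropped") for f in res.flags)
    with pytest.raises(DegenerateDataError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


# ------------------------------------------------------------------------ BH


def test_bh_hand_cases():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.005, 0.05, 0.5]) == pytest.approx([0.015, 0.075, 0.5])


def test_bh_properties():
    rng = np.random.Generator(np.random.PCG64(5))
    p = rng.uniform(size=40)
    q = bh_adjust(p)
    assert np.all(q >= p)
    # a second adjustment can only move q-values up, never down
    assert np.all(bh_adjust(q) >= q - 1e-12)
    # order-equivariant under permutation
    perm = rng.permutation(40)
    assert bh_adjust(p[perm]) == pytest.approx(q[perm])
    # monotone along sorted p
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_invariants_hold_for_arbitrary_p_vectors(p):
    q = bh_adjust(p)
    assert np.all((q >= np.asarray(p) - 1e-12) & (q <= 1.0 + 1e-12))
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=15),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=15),
)
def test_rank_biserial_bounds_for_arbitrary_samples(x, y):
    res = wilcoxon_rank_sum(x, y, exact_max_n=0)
    assert -1.0 <= res.effect_r <= 1.0
    assert 0.0 <= res.p <= 1.0


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.5])


# ---------------------------------------------------------------- effect sizes


def test_rank_biserial_unpaired_endpoints_and_hand_case():
    assert rank_biserial_unpaired(12, 3, 4) == 1.0
    assert rank_biserial_unpaired(6, 3, 4) == 0.0
    # complete separation x > y
    assert rank_biserial_unpaired(9, 3, 3) == 1.0
    with pytest.raises(ValueError):
        rank_biserial_unpaired(13, 3, 4)


def test_rank_biserial_unpaired_matches_pair_counting():
    rng = np.random.Generator(np.random.PCG64(11))
    for _ in range(20):
        n1, n2 = rng.integers(2, 20, size=2)
        if n1 * n2 > 400:
            continue
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        u1 = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        res = wilcoxon_rank_sum(x, y)
        assert res.effect_r == pytest.approx(2 * u1 / (n1 * n2) - 1)


def test_rank_biserial_paired_hand_case():
    # differences {3, -1, 2}: ranks {3, 1, 2}, W+=5, W-=1
    assert rank_biserial_paired(5, 1) == pytest.approx(4 / 6)
    assert rank_biserial_paired(10, 0) == 1.0
    assert rank_biserial_paired(4, 4) == 0.0
    with pytest.raises(DegenerateDataError):
        rank_biserial_paired(0, 0)


# ------------------------------------------------------------------- spearman


def test_spearman_perfect_monotone():
    x = np.arange(10.0)
    assert spearman(x, -x).rho == pytest.approx(-1.0)
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)  # monotone invariance


def test_spearman_hand_case():
    res = spearman([1, 2, 3], [3, 1, 2])
    assert res.rho == pytest.approx(-0.5)
    assert isinstance(res, CorrelationResult)


def test_spearman_exact_matches_scipy_direction():
    rng = np.random.Generator(np.random.PCG64(21))
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    exact = spearman(x, y)
    rho_ref, _ = sps.spearmanr(x, y)
    assert exact.rho == pytest.approx(rho_ref)
    assert 0.0 <= exact.p <= 1.0


def test_spearman_constant_input_errors():
    with pytest.raises(DegenerateDataError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------------- paired t


def test_paired_t_hand_case():
    res = paired_t([0.5, 1.0, 1.5, 2.0])
    assert res.statistic == pytest.approx(1.25 / (math.sqrt(1.25 / 3) / 2), rel=1e-6)


def test_paired_t_symmetric_gives_t_zero():
    res = paired_t([1.0, -1.0, 1.0, -1.0])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_paired_t_zero_variance_errors():
    with pytest.raises(DegenerateDataError):
        paired_t([2.0, 2.0, 2.0])


# -------------------------------------------------------------- assay ratios


def test_assay_ratio_identity_and_arithmetic():
    test = {f"i{k}": [10, 10] for k in range(6)}
    groups = {f"i{k}": ("HD" if k < 3 else "SMM") for k in range(6)}
    ratios, res = assay_ratio_compare(test, dict(test), groups)
    assert all(r == 1.0 for r in ratios.values())
    assert res.p == 1.0
    ratios, _ = assay_ratio_compare(
        {"a": [40, 60], "b": [10]}, {"a": [10, 10], "b": [10]}, {"a": "HD", "b": "SMM"}
    )
    assert ratios["a"] == 5.0


def test_assay_ratio_complete_separation():
    test = {"a": [50], "b": [60], "c": [5], "d": [6]}
    ctrl = {k: [10] for k in test}
    groups = {"a": "HD", "b": "HD", "c": "SMM", "d": "SMM"}
    _, res = assay_ratio_compare(test, ctrl, groups)
    assert res.effect_r == 1.0


def test_assay_ratio_zero_control_floored():
    ratios, res = assay_ratio_compare(
        {"a": [5], "b": [5], "c": [5], "d": [5]},
        {"a": [0], "b": [10], "c": [10], "d": [10]},
        {"a": "HD", "b": "HD", "c": "SMM", "d": "SMM"},
    )
    assert ratios["a"] == 10.0  # 5 / 0.5 floor
    assert any(f.startswith("zero_control") for f in res.flags)
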