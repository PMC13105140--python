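"""Shared statistical machinery: rank tests, BH correction, effect sizes.

Every comparison in the pipeline flows through this module so that the
conventions (two-sided tests, exact small-sample mode, rank-biserial effect
sizes, BH q-values computed per declared family) are applied uniformly.

Conventions
-----------
* Rank-sum tests report the Mann-Whitney U statistic for the *first* sample
  (U1); the unpaired rank-biserial effect is ``2*U1/(n1*n2) - 1`` so that
  r = +1 means the first group stochastically dominates.
* Signed-rank tests report W+ (sum of ranks of positive differences); the
  paired rank-biserial effect is ``(W+ - W-)/(W+ + W-)``.
* Exact p-values (full enumeration) are used when the smaller sample (or the
  number of nonzero differences) is at most ``exact_max_n`` and there are no
  ties; otherwise the normal approximation with tie and continuity
  corrections is used.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_EXACT_MAX_N = 8
#: sample size at or below which Spearman p-values are computed by full
#: permutation enumeration (untied data only)
SPEARMAN_EXACT_MAX_N = 9


class DegenerateDataError(ValueError):
    """Raised when a test is requested on data with no usable variation."""


@dataclass
class TestResult:
    """Universal comparison record: statistic, p, BH-q, rank-biserial r."""

    statistic: float
    p: float
    method: str
    n1: int
    n2: int
    q: float | None = None
    effect_r: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")
        if self.effect_r is not None and abs(self.effect_r) > 1 + 1e-12:
            raise ValueError(f"|effect_r| > 1: {self.effect_r}")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p": float(self.p),
            "q": None if self.q is None else float(self.q),
            "effect_r": None if self.effect_r is None else float(self.effect_r),
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
            "flags": list(self.flags),
        }


@dataclass
class CorrelationResult:
    """Spearman correlation with its two-sided p-value."""

    rho: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")

    def to_dict(self) -> dict:
        return {"rho": float(self.rho), "p": float(self.p), "n": self.n}


def _as_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def rank_biserial_unpaired(u1: float, n1: int, n2: int) -> float:
    """Rank-biserial r from the Mann-Whitney U statistic of group 1.

    r = 2*U1/(n1*n2) - 1, the difference between the probability that a
    group-1 value exceeds a group-2 value and the converse.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    if not (0.0 <= u1 <= n1 * n2):
        raise ValueError(f"U must lie in [0, n1*n2]; got {u1} for n1*n2={n1 * n2}")
    return 2.0 * u1 / (n1 * n2) - 1.0


def rank_biserial_paired(w_plus: float, w_minus: float) -> float:
    """Rank-biserial r from signed-rank statistics: (W+ - W-)/(W+ + W-)."""
    if w_plus < 0 or w_minus < 0:
        raise ValueError("rank sums must be nonnegative")
    total = w_plus + w_minus
    if total == 0:
        raise DegenerateDataError("no nonzero differences; paired effect undefined")
    return (w_plus - w_minus) / total


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration over rank splits when ``min(n1, n2) <= exact_max_n``
    and the pooled data are untied; otherwise normal approximation with tie
    and continuity corrections.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (min(n1, n2) <= exact_max_n) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    r = rank_biserial_unpaired(u1, n1, n2)
    return TestResult(
        statistic=u1,
        p=min(1.0, float(res.pvalue)),
        method=f"wilcoxon_rank_sum_{method}",
        n1=n1,
        n2=n2,
        effect_r=r,
        flags=["ties"] if has_ties else [],
    )


def _signed_rank_components(d: np.ndarray) -> tuple[float, float]:
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return w_plus, w_minus


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test on post - pre.

    Zero differences are dropped (count logged and flagged). Exact p by
    enumeration of sign patterns when the number of nonzero differences is at
    most ``exact_max_n`` and |differences| are untied.
    """
    pre_a = _as_1d(pre, "pre")
    post_a = _as_1d(post, "post")
    if pre_a.size != post_a.size:
        raise ValueError("pre and post must have equal length")
    return signed_rank_from_differences(post_a - pre_a, exact_max_n=exact_max_n)


def signed_rank_from_differences(
    diff: Sequence[float], exact_max_n: int = DEFAULT_EXACT_MAX_N
) -> TestResult:
    d = _as_1d(diff, "differences")
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n_zero:
        logger.info("signed-rank: dropped %d zero differences", n_zero)
    abs_ties = np.unique(np.abs(d)).size < d.size
    use_exact = (d.size <= exact_max_n) and not abs_ties
    mode = "exact" if use_exact else "approx"
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        mode=mode,
        correction=(mode == "approx"),
        zero_method="wilcox",
    )
    w_plus, w_minus = _signed_rank_components(d)
    flags = []
    if n_zero:
        flags.append(f"zero_diffs_dropped={n_zero}")
    if abs_ties:
        flags.append("ties")
    return TestResult(
        statistic=w_plus,
        p=min(1.0, float(res.pvalue)),
        method=f"wilcoxon_signed_rank_{mode}",
        n1=d.size,
        n2=d.size,
        effect_r=rank_biserial_paired(w_plus, w_minus),
        flags=flags,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = SPEARMAN_EXACT_MAX_N,
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Midranks handle ties. For untied samples with n <= ``exact_max_n`` the
    p-value is computed by full enumeration of the n! rank permutations;
    otherwise the t-distribution approximation is used.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise DegenerateDataError("constant input: Spearman rho undefined")
    rho, p_approx = sps.spearmanr(xa, ya)
    untied = np.unique(xa).size == n and np.unique(ya).size == n
    if untied and n <= exact_max_n:
        rx = sps.rankdata(xa)
        ry = sps.rankdata(ya)
        denom = n * (n * n - 1) / 6.0
        perms = np.array(list(itertools.permutations(ry)))
        rhos = 1.0 - np.sum((perms - rx) ** 2, axis=1) / denom
        rho_obs = 1.0 - float(np.sum((ry - rx) ** 2)) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        return CorrelationResult(rho=rho_obs, p=p, n=n)
    return CorrelationResult(rho=float(rho), p=float(p_approx), n=n)


def paired_t(diff: Sequence[float]) -> TestResult:
    """Two-sided one-sample t-test on paired differences."""
    d = _as_1d(diff, "differences")
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError("zero variance in differences; t undefined")
    res = sps.ttest_1samp(d, 0.0)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        method="paired_t",
        n1=d.size,
        n2=d.size,
    )


ZERO_CONTROL_FLOOR = 0.5  # half the minimum countable spot


def assay_ratio_compare(
    test_counts: Mapping[str, Sequence[float]],
    control_counts: Mapping[str, Sequence[float]],
    groups: Mapping[str, str],
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[dict[str, float], TestResult]:
    """Test-to-control assay ratios per individual, compared between groups.

    Replicates are averaged per individual; the ratio is mean(test) /
    mean(control).  A zero control mean is replaced by a floor of 0.5 (half
    the minimum countable unit) with a warning flag.  Exactly two groups are
    compared by the rank-sum test; the first group in sorted label order is
    group 1 of the result.
    """
    if set(test_counts) != set(control_counts) or set(test_counts) != set(groups):
        raise ValueError("test, control, and group maps must share the same individuals")
    ratios: dict[str, float] = {}
    flags: list[str] = []
    for ind in test_counts:
        t_mean = float(np.mean(np.asarray(test_counts[ind], dtype=float)))
        c_mean = float(np.mean(np.asarray(control_counts[ind], dtype=float)))
        if c_mean <= 0:
            logger.warning("zero control mean for %s; floored at %s", ind, ZERO_CONTROL_FLOOR)
            flags.append(f"zero_control:{ind}")
            c_mean = ZERO_CONTROL_FLOOR
        ratios[ind] = t_mean / c_mean
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g1 = [ratios[i] for i in ratios if groups[i] == labels[0]]
    g2 = [ratios[i] for i in ratios if groups[i] == labels[1]]
    result = wilcoxon_rank_sum(g1, g2, exact_max_n=exact_max_n)
    result.flags.extend(flags)
    return ratios, result
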