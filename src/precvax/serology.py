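"""Antibody-titer analyses: windowed cross-sectional comparisons and the
longitudinal random-intercept mixed model of waning with a likelihood-ratio
test for slope heterogeneity.

Model
-----
For individual i in disease group g(i) sampled at day d::

    log(titer)_ij = alpha_{g(i)} + beta_{g(i)} * d_ij + u_i + eps_ij

with u_i ~ N(0, sigma_u^2) and eps ~ N(0, sigma_e^2).  Fitting is by
maximum likelihood (not REML) because the likelihood-ratio test compares
fixed-effect structures.  The fixed effects are profiled out by generalized
least squares at each variance-component iterate; with a single random
intercept the covariance inverse and determinant are analytic per
individual, so the profile likelihood is one-dimensional in the variance
ratio lambda = sigma_u^2 / sigma_e^2 and is optimized on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import TestResult, bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

KINETICS_WINDOW = (14, 120)
KINETICS_GROUPS = ("MGUS", "SMM")
LOGLIK_TOL = 1e-8


# ------------------------------------------------------------ window filters


def window_filter(
    observations: pd.DataFrame,
    window: tuple[int, int],
    dose_index: int = 2,
) -> pd.DataFrame:
    """Keep, per individual, the earliest sample inside a closed day window.

    Observations outside ``[day_lo, day_hi]`` (or from another dose) are
    dropped.  A same-day tie keeps the first row in file order (warned).
    """
    df = observations
    if "dose" in df.columns:
        df = df[df["dose"] == dose_index]
    lo, hi = window
    df = df[(df["days_post_dose2"] >= lo) & (df["days_post_dose2"] <= hi)]
    if df.empty:
        logger.info("window %s: no observations remain", window)
        return df.copy()
    # stable sort preserves file order among same-day ties
    df = df.sort_values("days_post_dose2", kind="stable")
    dupes = df.duplicated(subset="individual_id", keep="first")
    first = df[~dupes]
    same_day = df.merge(
        first[["individual_id", "days_post_dose2"]],
        on=["individual_id", "days_post_dose2"],
    )
    if len(same_day) > len(first):
        logger.warning("window %s: same-day tie(s) resolved by file order", window)
    return first.sort_index()


def cross_sectional_compare(
    observations: pd.DataFrame,
    reference_group: str = "HD",
    exact_max_n: int = 8,
) -> dict[str, TestResult]:
    """Rank-sum tests of each group vs the reference on log titers.

    The BH family is the set of comparisons within this panel; effect sizes
    are computed always and flagged visible at q < 0.1.
    """
    present = [g for g in observations["group"].unique() if g != reference_group]
    ref = observations.loc[observations["group"] == reference_group, "log_titer"]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} absent")
    results: dict[str, TestResult] = {}
    for g in sorted(present):
        vals = observations.loc[observations["group"] == g, "log_titer"]
        results[g] = wilcoxon_rank_sum(vals, ref, exact_max_n=exact_max_n)
    qs = bh_adjust([results[g].p for g in sorted(present)])
    for g, q in zip(sorted(present), qs):
        results[g].q = float(q)
        if q < 0.1:
            results[g].flags.append("effect_reported")
    return results


def eligible_for_kinetics(
    observations: pd.DataFrame,
    groups: tuple[str, ...] = KINETICS_GROUPS,
    window: tuple[int, int] = KINETICS_WINDOW,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Restrict to configured groups and individuals with >= 2 in-window samples."""
    lo, hi = window
    df = observations[observations["group"].isin(groups)]
    df = df[(df["days_post_dose2"] >= lo) & (df["days_post_dose2"] <= hi)]
    counts = df.groupby("individual_id")["days_post_dose2"].transform("size")
    return df[counts >= min_samples].copy()


# --------------------------------------------------------------- mixed model


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the random-intercept waning model."""

    intercept_per_group: dict[str, float]
    slope_per_group: dict[str, float]
    sigma_u: float
    sigma_e: float
    loglik: float
    n_individuals: int
    n_obs: int
    converged: bool
    slope_mode: str
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "intercept_per_group": self.intercept_per_group,
            "slope_per_group": self.slope_per_group,
            "sigma_u": self.sigma_u,
            "sigma_e": self.sigma_e,
            "loglik": self.loglik,
            "n_individuals": self.n_individuals,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "slope_mode": self.slope_mode,
            "flags": self.flags,
        }


@dataclass
class LrtResult:
    """Likelihood-ratio test of group-specific vs common waning slopes."""

    stat: float
    df: int
    p: float
    loglik_full: float
    loglik_constrained: float

    def to_dict(self) -> dict:
        return {
            "stat": self.stat,
            "df": self.df,
            "p": self.p,
            "loglik_full": self.loglik_full,
            "loglik_constrained": self.loglik_constrained,
        }


def _design(df: pd.DataFrame, groups: list[str], slope_mode: str) -> np.ndarray:
    g_idx = pd.Categorical(df["group"], categories=groups).codes
    days = df["days_post_dose2"].to_numpy(dtype=float)
    n = len(df)
    G = len(groups)
    if slope_mode == "group_specific":
        X = np.zeros((n, 2 * G))
        X[np.arange(n), g_idx] = 1.0
        X[np.arange(n), G + g_idx] = days
    elif slope_mode == "common":
        X = np.zeros((n, G + 1))
        X[np.arange(n), g_idx] = 1.0
        X[:, G] = days
    else:
        raise ValueError(f"unknown slope_mode {slope_mode!r}")
    return X


def _profile_loglik(lam: float, blocks: list[tuple[np.ndarray, np.ndarray]]):
    """Concentrated ML log-likelihood at variance ratio lam; returns
    (loglik, beta, sigma_e2)."""
    p = blocks[0][0].shape[1]
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    logdet = 0.0
    N = 0
    for Xi, yi in blocks:
        ni = len(yi)
        w = lam / (1.0 + lam * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        xtx += Xi.T @ Xi - w * np.outer(sx, sx)
        xty += Xi.T @ yi - w * sx * sy
        logdet += np.log1p(lam * ni)
        N += ni
    beta = np.linalg.solve(xtx, xty)
    rss = 0.0
    for Xi, yi in blocks:
        ri = yi - Xi @ beta
        w = lam / (1.0 + lam * len(yi))
        rss += ri @ ri - w * ri.sum() ** 2
    sigma_e2 = rss / N
    ll = -0.5 * (N * np.log(2 * np.pi) + N * np.log(sigma_e2) + logdet + N)
    return ll, beta, sigma_e2


def fit_waning_lmm(
    observations: pd.DataFrame,
    slope_mode: str = "group_specific",
    groups: tuple[str, ...] | None = None,
) -> LmmFit:
    """Fit the random-intercept waning model by concentrated ML.

    Observations need columns ``individual_id, group, days_post_dose2,
    log_titer``; each individual must belong to exactly one group and each
    group must contribute at least 2 individuals.
    """
    df = observations
    if groups is None:
        groups = tuple(sorted(df["group"].unique()))
    df = df[df["group"].isin(groups)]
    per_ind_groups = df.groupby("individual_id")["group"].nunique()
    if (per_ind_groups > 1).any():
        raise ValueError("an individual is assigned to more than one group")
    n_per_group = df.groupby("group")["individual_id"].nunique()
    if (n_per_group < 2).any():
        raise ValueError(f"need >= 2 individuals per group, got {dict(n_per_group)}")

    glist = list(groups)
    X = _design(df, glist, slope_mode)
    y = df["log_titer"].to_numpy(dtype=float)
    ind_codes = pd.Categorical(df["individual_id"]).codes
    order = np.argsort(ind_codes, kind="stable")
    Xs, ys, codes = X[order], y[order], ind_codes[order]
    bounds = np.searchsorted(codes, np.unique(codes))
    blocks = [
        (Xs[a:b], ys[a:b])
        for a, b in zip(bounds, list(bounds[1:]) + [len(codes)])
    ]

    def neg_ll(eta: float) -> float:
        return -_profile_loglik(np.exp(eta), blocks)[0]

    opt = optimize.minimize_scalar(
        neg_ll, bounds=(-15.0, 12.0), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    ll_opt, beta_opt, s2_opt = _profile_loglik(np.exp(opt.x), blocks)
    ll_zero, beta_zero, s2_zero = _profile_loglik(0.0, blocks)
    flags: list[str] = []
    if ll_zero >= ll_opt - LOGLIK_TOL:
        lam, ll, beta, s2 = 0.0, ll_zero, beta_zero, s2_zero
        flags.append("singular_fit")  # degenerates to pooled regression
    else:
        lam, ll, beta, s2 = float(np.exp(opt.x)), ll_opt, beta_opt, s2_opt
    converged = bool(opt.success) or "singular_fit" in flags
    if not converged:
        flags.append("non_converged")
        logger.warning("LMM optimizer did not converge: %s", opt.message)

    G = len(glist)
    intercepts = {g: float(beta[i]) for i, g in enumerate(glist)}
    if slope_mode == "group_specific":
        slopes = {g: float(beta[G + i]) for i, g in enumerate(glist)}
    else:
        slopes = {g: float(beta[G]) for g in glist}
    return LmmFit(
        intercept_per_group=intercepts,
        slope_per_group=slopes,
        sigma_u=float(np.sqrt(lam * s2)),
        sigma_e=float(np.sqrt(s2)),
        loglik=float(ll),
        n_individuals=len(blocks),
        n_obs=len(y),
        converged=converged,
        slope_mode=slope_mode,
        flags=flags,
    )


def lrt_slope_heterogeneity(
    observations: pd.DataFrame, groups: tuple[str, ...] | None = None
) -> LrtResult:
    """LRT of group-specific vs common waning slopes (chi-square reference)."""
    full = fit_waning_lmm(observations, "group_specific", groups=groups)
    constrained = fit_waning_lmm(observations, "common", groups=groups)
    if not (full.converged and constrained.converged):
        raise RuntimeError(
            f"non-converged nested fits: full={full.flags}, constrained={constrained.flags}"
        )
    stat = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    df_ = len(full.slope_per_group) - 1
    p = float(sps.chi2.sf(stat, df_)) if df_ > 0 else 1.0
    return LrtResult(
        stat=float(stat),
        df=df_,
        p=p,
        loglik_full=full.loglik,
        loglik_constrained=constrained.loglik,
    )
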