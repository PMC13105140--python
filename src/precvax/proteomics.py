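"""Olink-style NPX panels: paired vaccination-response tests, cross-group
panels, and the APRIL-tumor-burden correlation.

NPX values are Olink's arbitrary log2-scale unit and are taken as provided
(no renormalization or QC).  Two BH family conventions are supported for the
paired panel because both appear in practice: per protein across disease
groups (3 tests per cytokine) and per group across all proteins on the
panel; switching the family changes q-values but never p-values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import (
    CorrelationResult,
    DegenerateDataError,
    bh_adjust,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)

FAMILY_MODES = ("per_protein_across_groups", "per_group_across_proteins")
MIN_PAIRS = 3
EFFECT_VISIBILITY_Q = 0.1


def _paired_wide(npx: pd.DataFrame) -> pd.DataFrame:
    wide = npx.pivot_table(
        index=["protein", "individual_id", "group"],
        columns="timepoint", values="npx", aggfunc="first",
    ).reset_index()
    return wide.dropna(subset=["pre", "post"])


def paired_response_panel(
    npx: pd.DataFrame,
    family_mode: str = "per_protein_across_groups",
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Signed-rank post-vs-pre tests per (protein, group), BH per family.

    Only individuals with both timepoints enter each test.  Rows with fewer
    than 3 pairs are flagged underpowered (p still computed).  Effect sizes
    (paired rank-biserial) are always computed; ``effect_visible`` marks the
    q < 0.1 reporting rule.
    """
    if family_mode not in FAMILY_MODES:
        raise ValueError(f"family_mode must be one of {FAMILY_MODES}")
    wide = _paired_wide(npx)
    rows = []
    for (protein, group), sub in wide.groupby(["protein", "group"], sort=True):
        diffs = sub["post"] - sub["pre"]
        try:
            res = wilcoxon_signed_rank(sub["pre"], sub["post"], exact_max_n=exact_max_n)
            stat, p, effect = res.statistic, res.p, res.effect_r
        except DegenerateDataError:
            # no change in any pair: no evidence against the null
            logger.info("%s/%s: all paired differences zero", protein, group)
            stat, p, effect = np.nan, 1.0, 0.0
        rows.append(
            {
                "protein": protein,
                "group": group,
                "n_pairs": len(sub),
                "direction": float(np.sign(diffs.median())),
                "statistic": stat,
                "p": p,
                "effect_r": effect,
                "underpowered": len(sub) < MIN_PAIRS,
                "family_mode": family_mode,
            }
        )
    out = pd.DataFrame(rows)
    family_col = "protein" if family_mode == "per_protein_across_groups" else "group"
    out["q"] = np.nan
    for _, idx in out.groupby(family_col).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"])
    out["effect_visible"] = out["q"] < EFFECT_VISIBILITY_Q
    return out


def cross_group_panel(
    npx: pd.DataFrame, timepoint: str, exact_max_n: int = 8
) -> pd.DataFrame:
    """All pairwise group rank-sum tests per protein at one timepoint.

    A single BH family spans all (protein x group-pair) tests within the
    timepoint — e.g. 52 proteins x 3 pairs = 156 tests.
    """
    sub = npx[npx["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no records at timepoint {timepoint!r}")
    groups = sorted(sub["group"].unique())
    rows = []
    for protein, prot_df in sub.groupby("protein", sort=True):
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                x = prot_df.loc[prot_df["group"] == g1, "npx"]
                y = prot_df.loc[prot_df["group"] == g2, "npx"]
                if x.empty or y.empty:
                    continue
                res = wilcoxon_rank_sum(x, y, exact_max_n=exact_max_n)
                rows.append(
                    {
                        "protein": protein,
                        "group1": g1,
                        "group2": g2,
                        "timepoint": timepoint,
                        "n1": res.n1,
                        "n2": res.n2,
                        "statistic": res.statistic,
                        "p": res.p,
                        "effect_r": res.effect_r,
                    }
                )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["effect_visible"] = out["q"] < EFFECT_VISIBILITY_Q
    return out


def burden_correlation(
    npx: pd.DataFrame,
    burden: Mapping[str, float] | pd.Series,
    protein: str = "TNFSF13",
    timepoint: str = "post",
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Spearman correlation of one analyte with a per-individual tumor-burden
    covariate (M-spike, g/dL); returns the result and the scatter table."""
    if isinstance(burden, pd.Series):
        burden = burden.to_dict()
    sub = npx[(npx["protein"] == protein) & (npx["timepoint"] == timepoint)]
    sub = sub[sub["individual_id"].isin(burden)]
    if len(sub) < 3:
        raise ValueError("need at least 3 complete (analyte, burden) pairs")
    scatter = pd.DataFrame(
        {
            "individual_id": sub["individual_id"].to_numpy(),
            "m_spike": [burden[i] for i in sub["individual_id"]],
            "npx": sub["npx"].to_numpy(),
        }
    )
    result = spearman(scatter["m_spike"], scatter["npx"])
    return result, scatter
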