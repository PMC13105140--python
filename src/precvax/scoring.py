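"""Gene-module scoring with expression-matched control genes, patient-level
aggregation, group tests, and the external-validation procedures for the
APRIL-responsive module.

The per-cell score of a module is the mean log-normalized expression of the
module genes minus the mean over a control pool: for each module gene,
``ctrl_per_gene`` genes are sampled (seeded, without replacement, module
genes excluded) from the same average-expression bin, and the union of the
samples forms the pool.  With ``ctrl_per_gene`` large enough to exhaust
every bin the pool is the whole matched background and scores are
seed-independent.  Bins are computed on the cell subset being scored, which
changes values relative to binning on a full matrix — deliberate, and
matching the behavior of the standard single-cell scoring function on
subset inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .io import CellMatrix
from .stats import (
    TestResult,
    bh_adjust,
    paired_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 25
DEFAULT_CTRL_PER_GENE = 50


def log_normalize(cm: CellMatrix, target_sum: float = 1e4) -> CellMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p."""
    if cm.normalized:
        raise ValueError("matrix is already normalized")
    totals = np.asarray(cm.X.sum(axis=1)).ravel()
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        ids = cm.cell_meta.iloc[zero[0]].to_dict()
        raise ValueError(f"all-zero cell at row {zero[0]}: {ids}")
    X = cm.X.astype(float).tocsr(copy=True)
    scale = target_sum / totals
    X = sparse.diags(scale) @ X
    X.data = np.log1p(X.data)
    return CellMatrix(
        X=X.tocsr(), gene_names=list(cm.gene_names),
        cell_meta=cm.cell_meta.copy(), normalized=True,
    )


@dataclass
class ModuleScoreTable:
    """Per-cell module scores with the metadata needed for aggregation."""

    scores: np.ndarray  # one per cell
    cell_meta: pd.DataFrame
    module_genes_used: list[str]
    n_module_dropped: int
    n_bins: int
    ctrl_per_gene: int
    seed: int
    exhaustive_controls: bool

    def per_patient(
        self, by: Sequence[str] = ("individual_id", "timepoint", "cell_type")
    ) -> pd.DataFrame:
        """Mean score per (individual, timepoint, cell-type stratum)."""
        df = self.cell_meta.copy()
        df["score"] = self.scores
        keep_cols = [c for c in ("group",) if c in df.columns]
        grouped = df.groupby(list(by), sort=True, observed=True)
        out = grouped["score"].mean().reset_index()
        if keep_cols:
            labels = grouped[keep_cols].first().reset_index(drop=True)
            out = pd.concat([out, labels], axis=1)
        return out


def score_gene_module(
    cm: CellMatrix,
    module: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    ctrl_per_gene: int = DEFAULT_CTRL_PER_GENE,
    seed: int = 0,
) -> ModuleScoreTable:
    """Score a gene module against expression-matched control genes.

    Requires a log-normalized matrix.  Module genes absent from the matrix
    are dropped with a logged count; an empty intersection is an error.
    """
    if not cm.normalized:
        raise ValueError("score_gene_module expects a log-normalized matrix")
    present = [g for g in module if g in set(cm.gene_names)]
    n_dropped = len(module) - len(present)
    if not present:
        raise ValueError("no module gene is present in the matrix")
    if n_dropped:
        logger.info("module: %d genes absent from matrix, dropped", n_dropped)

    gene_index = {g: i for i, g in enumerate(cm.gene_names)}
    mod_idx = np.array([gene_index[g] for g in present], dtype=int)
    avg = np.asarray(cm.X.mean(axis=0)).ravel()
    n_genes = avg.size
    # equal-occupancy bins on the rank of average expression
    order_rank = pd.Series(avg).rank(method="first").to_numpy()
    bin_of = np.floor((order_rank - 1) / n_genes * n_bins).astype(int)
    bin_of = np.clip(bin_of, 0, n_bins - 1)

    rng = np.random.Generator(np.random.PCG64(seed))
    mod_set = set(mod_idx.tolist())
    control: set[int] = set()
    exhaustive = True
    for gi in mod_idx:
        candidates = np.nonzero(bin_of == bin_of[gi])[0]
        candidates = np.array([c for c in candidates if c not in mod_set])
        if candidates.size == 0:
            continue
        if candidates.size <= ctrl_per_gene:
            control.update(candidates.tolist())
        else:
            exhaustive = False
            picked = rng.choice(candidates, size=ctrl_per_gene, replace=False)
            control.update(picked.tolist())
    if not control:
        raise ValueError("empty control pool; increase n_genes or reduce n_bins")
    ctrl_idx = np.array(sorted(control), dtype=int)

    mod_mean = np.asarray(cm.X[:, mod_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(cm.X[:, ctrl_idx].mean(axis=1)).ravel()
    return ModuleScoreTable(
        scores=mod_mean - ctrl_mean,
        cell_meta=cm.cell_meta.copy(),
        module_genes_used=present,
        n_module_dropped=n_dropped,
        n_bins=n_bins,
        ctrl_per_gene=ctrl_per_gene,
        seed=seed,
        exhaustive_controls=exhaustive,
    )


def compare_patient_scores(
    table: ModuleScoreTable,
    groups: tuple[str, str],
    timepoint: str | None = None,
    cell_type: str | None = None,
    exact_max_n: int = 8,
) -> TestResult:
    """Rank-sum test on per-patient mean scores within a stratum.

    Patients with zero cells in the stratum simply do not appear (logged).
    """
    df = table.cell_meta.copy()
    df["score"] = table.scores
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    per_patient = df.groupby(["individual_id", "group"], observed=True)["score"].mean()
    per_patient = per_patient.reset_index()
    g1 = per_patient.loc[per_patient["group"] == groups[0], "score"]
    g2 = per_patient.loc[per_patient["group"] == groups[1], "score"]
    if g1.empty or g2.empty:
        raise ValueError(f"no patients in stratum for one of {groups}")
    return wilcoxon_rank_sum(g1, g2, exact_max_n=exact_max_n)


def pergene_group_test(
    cm: CellMatrix,
    module: Sequence[str],
    groups: tuple[str, str],
    timepoint: str | None = None,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Cell-level rank-sum test per module gene, BH across module genes.

    Returns one row per present module gene with statistic, p, q, effect_r,
    and the direction of the group-1 minus group-2 mean difference.  Absent
    genes are omitted from the family.
    """
    if not cm.normalized:
        raise ValueError("pergene_group_test expects a log-normalized matrix")
    mask = cm.cell_meta["group"].isin(groups).to_numpy()
    if timepoint is not None:
        mask &= (cm.cell_meta["timepoint"] == timepoint).to_numpy()
    if cell_type is not None:
        mask &= (cm.cell_meta["cell_type"] == cell_type).to_numpy()
    meta = cm.cell_meta[mask]
    X = cm.X[mask]
    in_g1 = (meta["group"] == groups[0]).to_numpy()
    gene_set = set(cm.gene_names)
    present = [g for g in module if g in gene_set]
    rows = []
    for g in present:
        col = np.asarray(X[:, cm.gene_names.index(g)].todense()).ravel()
        res = wilcoxon_rank_sum(col[in_g1], col[~in_g1], exact_max_n=0)
        rows.append(
            {
                "gene": g,
                "statistic": res.statistic,
                "p": res.p,
                "effect_r": res.effect_r,
                "direction": float(np.sign(col[in_g1].mean() - col[~in_g1].mean())),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out


def validate_timecourse(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    module: Sequence[str],
    baseline_timepoint,
) -> pd.DataFrame:
    """Paired time-course validation of a module on bulk expression.

    ``expr`` is samples x genes (index = sample id); ``design`` maps sample
    id to (donor, timepoint).  For every non-baseline timepoint, the paired
    per-donor difference vs baseline is tested per gene with a two-sided
    paired t-test; BH is applied within each timepoint's module family.
    A gene is called significantly upregulated at q < 0.05 with a positive
    mean difference.  Donors missing a timepoint are dropped for that
    timepoint (logged).
    """
    for col in ("donor", "timepoint"):
        if col not in design.columns:
            raise ValueError(f"design must have a {col!r} column")
    design = design.set_index(design.index if "sample" not in design.columns else design["sample"])
    present = [g for g in module if g in expr.columns]
    if not present:
        raise ValueError("no module gene present in expression matrix")
    base = design[design["timepoint"] == baseline_timepoint]
    if base.empty:
        raise ValueError(f"baseline timepoint {baseline_timepoint!r} absent from design")
    base_sample_of = dict(zip(base["donor"], base.index))
    rows = []
    for tp in [t for t in design["timepoint"].unique() if t != baseline_timepoint]:
        sub = design[design["timepoint"] == tp]
        donors = [d for d in sub["donor"] if d in base_sample_of]
        dropped = set(sub["donor"]) - set(donors)
        if dropped:
            logger.info("timepoint %s: donors %s lack baseline, dropped", tp, sorted(dropped))
        tp_sample_of = dict(zip(sub["donor"], sub.index))
        tp_rows = []
        for g in present:
            diffs = [
                expr.at[tp_sample_of[d], g] - expr.at[base_sample_of[d], g] for d in donors
            ]
            if np.std(diffs, ddof=1) == 0:
                # degenerate pairing: identical differences carry no
                # within-donor variability for the t statistic
                mean = float(np.mean(diffs))
                t_stat, p = (0.0, 1.0) if mean == 0 else (np.inf, 0.0)
                logger.warning("timepoint %s gene %s: zero-variance differences", tp, g)
            else:
                res = paired_t(diffs)
                t_stat, p = res.statistic, res.p
            tp_rows.append(
                {
                    "timepoint": tp,
                    "gene": g,
                    "mean_diff": float(np.mean(diffs)),
                    "t": t_stat,
                    "p": p,
                    "n_donors": len(donors),
                }
            )
        qs = bh_adjust([r["p"] for r in tp_rows])
        for r, q in zip(tp_rows, qs):
            r["q"] = float(q)
            r["significant_up"] = bool(q < 0.05 and r["mean_diff"] > 0)
        rows.extend(tp_rows)
    return pd.DataFrame(rows)


def validate_external_plasma_cells(
    cm: CellMatrix,
    module: Sequence[str],
    groups: tuple[str, str] = ("NBM", "SMM"),
    n_bins: int = DEFAULT_N_BINS,
    ctrl_per_gene: int = DEFAULT_CTRL_PER_GENE,
    seed: int = 0,
) -> tuple[TestResult, pd.DataFrame]:
    """Sample-level module comparison in an external plasma-cell cohort.

    Composition of log-normalization, module scoring, per-sample mean
    aggregation, and a two-group rank-sum test.  Also returns the per-gene
    rank-sum table (with direction) for cross-dataset concordance checks.
    """
    norm = log_normalize(cm) if not cm.normalized else cm
    table = score_gene_module(norm, module, n_bins=n_bins, ctrl_per_gene=ctrl_per_gene, seed=seed)
    result = compare_patient_scores(table, groups=groups)
    pergene = pergene_group_test(norm, module, groups=groups)
    return result, pergene


def concordance_table(pergene_a: pd.DataFrame, pergene_b: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-gene direction-of-effect concordance between two datasets."""
    merged = pergene_a.merge(pergene_b, on="gene", suffixes=("_a", "_b"))
    merged["concordant"] = merged["direction_a"] == merged["direction_b"]
    return merged[["gene", "direction_a", "direction_b", "concordant"]]


def score_signature_across_cell_types(
    cm: CellMatrix,
    signature: Sequence[str],
    n_bins: int = DEFAULT_N_BINS,
    ctrl_per_gene: int = DEFAULT_CTRL_PER_GENE,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient signature scores averaged across cell types.

    Each cell type is scored separately (bins computed within the cell
    type), scores are averaged per (patient, timepoint, cell type), then
    across cell types — the aggregation used for broad response signatures
    such as the IL-1beta module.
    """
    if not cm.normalized:
        raise ValueError("expects a log-normalized matrix")
    pieces = []
    for ct in sorted(cm.cell_meta["cell_type"].unique()):
        mask = (cm.cell_meta["cell_type"] == ct).to_numpy()
        sub = CellMatrix(
            X=cm.X[mask], gene_names=list(cm.gene_names),
            cell_meta=cm.cell_meta[mask].reset_index(drop=True), normalized=True,
        )
        table = score_gene_module(sub, signature, n_bins=n_bins,
                                  ctrl_per_gene=ctrl_per_gene, seed=seed)
        pieces.append(table.per_patient())
    all_ct = pd.concat(pieces, ignore_index=True)
    keep = [c for c in ("group",) if c in all_ct.columns]
    grouped = all_ct.groupby(["individual_id", "timepoint"], observed=True)
    out = grouped["score"].mean().reset_index()
    if keep:
        out = out.merge(
            all_ct[["individual_id"] + keep].drop_duplicates("individual_id"),
            on="individual_id",
        )
    return out


def paired_signature_test(
    per_patient: pd.DataFrame, group: str, exact_max_n: int = 8
) -> TestResult:
    """Paired signed-rank pre/post test of patient-level signature scores,
    restricted to individuals with both timepoints."""
    df = per_patient[per_patient["group"] == group]
    wide = df.pivot(index="individual_id", columns="timepoint", values="score")
    wide = wide.dropna(subset=["pre", "post"])
    if wide.empty:
        raise ValueError(f"no paired individuals in group {group!r}")
    return wilcoxon_signed_rank(wide["pre"], wide["post"], exact_max_n=exact_max_n)
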