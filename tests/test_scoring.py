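"""Module scoring: normalization, control matching, linearity, aggregation,
group tests, and the external-validation procedures on constructed data.
scanpy's score_genes serves as an independent cross-check, never as the
implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from precvax.io import CellMatrix
from precvax.scoring import (
    ModuleScoreTable,
    compare_patient_scores,
    concordance_table,
    log_normalize,
    paired_signature_test,
    pergene_group_test,
    score_gene_module,
    score_signature_across_cell_types,
    validate_external_plasma_cells,
    validate_timecourse,
)
from precvax.synth import APRIL_MODULE, ExprSimConfig, simulate_expression_cohort


def _toy_matrix(values, genes, meta=None):
    n = values.shape[0]
    meta = meta if meta is not None else pd.DataFrame(
        {
            "individual_id": [f"p{i}" for i in range(n)],
            "group": ["HD"] * n,
            "timepoint": ["post"] * n,
            "cell_type": ["B"] * n,
        }
    )
    return CellMatrix(
        X=sparse.csr_matrix(values.astype(float)), gene_names=genes,
        cell_meta=meta, normalized=True,
    )


# --------------------------------------------------------------- normalize


def test_log_normalize_arithmetic():
    counts = np.zeros((1, 5))
    counts[0, 0] = 10
    cm = CellMatrix(
        X=sparse.csr_matrix(counts), gene_names=list("abcde"),
        cell_meta=pd.DataFrame({"individual_id": ["p0"], "group": ["HD"],
                                "timepoint": ["post"], "cell_type": ["B"]}),
    )
    norm = log_normalize(cm)
    assert norm.X[0, 0] == pytest.approx(np.log1p(10_000))


def test_log_normalize_all_zero_cell_errors():
    counts = np.array([[1, 2], [0, 0]])
    cm = CellMatrix(
        X=sparse.csr_matrix(counts), gene_names=["a", "b"],
        cell_meta=pd.DataFrame({"individual_id": ["p0", "p1"], "group": ["HD"] * 2,
                                "timepoint": ["post"] * 2, "cell_type": ["B"] * 2}),
    )
    with pytest.raises(ValueError, match="all-zero cell"):
        log_normalize(cm)


def test_log_normalize_scale_invariance():
    rng = np.random.Generator(np.random.PCG64(1))
    counts = rng.integers(0, 20, size=(4, 30))
    counts[:, 0] += 1
    meta = pd.DataFrame({"individual_id": [f"p{i}" for i in range(4)],
                         "group": ["HD"] * 4, "timepoint": ["post"] * 4,
                         "cell_type": ["B"] * 4})
    genes = [f"g{i}" for i in range(30)]
    a = log_normalize(CellMatrix(X=sparse.csr_matrix(counts), gene_names=genes, cell_meta=meta))
    b = log_normalize(CellMatrix(X=sparse.csr_matrix(counts * 2), gene_names=genes, cell_meta=meta))
    assert np.allclose(a.X.toarray(), b.X.toarray())


# ------------------------------------------------------------------ scoring


def test_score_exact_linearity():
    """Adding c to every module gene of a cell raises its score by exactly c."""
    rng = np.random.Generator(np.random.PCG64(3))
    vals = rng.uniform(0, 3, size=(6, 40))
    genes = [f"g{i}" for i in range(40)]
    module = ["g0", "g1", "g2"]
    cm = _toy_matrix(vals, genes)
    base = score_gene_module(cm, module, n_bins=4, ctrl_per_gene=1000, seed=0)
    shifted_vals = vals.copy()
    shifted_vals[2, :3] += 0.7
    # same control pool: exhaustive mode is seed- and data-order independent
    cm2 = _toy_matrix(shifted_vals, genes)
    shifted = score_gene_module(cm2, module, n_bins=4, ctrl_per_gene=1000, seed=0)
    delta = shifted.scores - base.scores
    assert delta[2] == pytest.approx(0.7)
    assert np.allclose(np.delete(delta, 2), 0.0, atol=1e-9)


def test_score_exhaustive_controls_closed_form_and_seed_free():
    vals = np.array([[1.0, 2.0, 3.0, 4.0], [0.5, 1.5, 2.5, 3.5]])
    genes = ["m1", "m2", "c1", "c2"]
    cm = _toy_matrix(vals, genes)
    t1 = score_gene_module(cm, ["m1", "m2"], n_bins=1, ctrl_per_gene=99, seed=0)
    t2 = score_gene_module(cm, ["m1", "m2"], n_bins=1, ctrl_per_gene=99, seed=77)
    expected = vals[:, :2].mean(axis=1) - vals[:, 2:].mean(axis=1)
    assert t1.scores == pytest.approx(expected)
    assert t2.scores == pytest.approx(t1.scores)
    assert t1.exhaustive_controls


def test_score_random_module_null():
    rng = np.random.Generator(np.random.PCG64(8))
    vals = rng.uniform(0, 2, size=(200, 300))
    genes = [f"g{i}" for i in range(300)]
    cm = _toy_matrix(vals, genes)
    module = [f"g{i}" for i in rng.choice(300, size=10, replace=False)]
    tab = score_gene_module(cm, module, seed=1)
    se = tab.scores.std(ddof=1) / np.sqrt(len(tab.scores))
    assert abs(tab.scores.mean()) < 3 * se + 0.01


def test_score_missing_module_genes_dropped_or_error():
    vals = np.ones((2, 60))
    genes = [f"g{i}" for i in range(60)]
    cm = _toy_matrix(vals, genes)
    tab = score_gene_module(cm, ["g0", "NOPE"], n_bins=1, ctrl_per_gene=100, seed=0)
    assert tab.n_module_dropped == 1
    with pytest.raises(ValueError, match="no module gene"):
        score_gene_module(cm, ["NOPE"], seed=0)


def test_patient_aggregation_commutes_with_cell_permutation():
    cfg = ExprSimConfig(n_patients=3, n_cells_per_patient=15, n_genes=300,
                        module_shift=0.4, seed=6)
    cm, _ = simulate_expression_cohort(cfg)
    norm = log_normalize(cm)
    tab = score_gene_module(norm, APRIL_MODULE, seed=0)
    perm = np.random.Generator(np.random.PCG64(0)).permutation(norm.n_cells)
    permuted = ModuleScoreTable(
        scores=tab.scores[perm], cell_meta=tab.cell_meta.iloc[perm].reset_index(drop=True),
        module_genes_used=tab.module_genes_used, n_module_dropped=0,
        n_bins=tab.n_bins, ctrl_per_gene=tab.ctrl_per_gene, seed=0,
        exhaustive_controls=tab.exhaustive_controls,
    )
    a = tab.per_patient().sort_values(["individual_id", "timepoint"]).reset_index(drop=True)
    b = permuted.per_patient().sort_values(["individual_id", "timepoint"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_scanpy_cross_check_recovered_shift():
    """Independent scorer (scanpy score_genes) recovers the same planted
    shift as the package's scorer on the same cohort."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad

    cfg = ExprSimConfig(n_patients=10, n_cells_per_patient=30, n_genes=600,
                        module_shift=0.4, seed=11)
    cm, _ = simulate_expression_cohort(cfg)
    norm = log_normalize(cm)
    tab = score_gene_module(norm, APRIL_MODULE, seed=0)
    adata = ad.AnnData(X=norm.X.copy(), obs=norm.cell_meta.copy(),
                       var=pd.DataFrame(index=norm.gene_names))
    sc.tl.score_genes(adata, APRIL_MODULE, score_name="sc_score", random_state=0)
    obs = adata.obs.assign(ours=tab.scores)

    def recovered(col):
        pp = obs.groupby(["individual_id", "group", "timepoint"], observed=True)[col].mean()
        pp = pp.reset_index()
        post = pp[pp["timepoint"] == "post"]
        return (post[post["group"] == "SMM"][col].mean()
                - post[post["group"] == "HD"][col].mean())

    assert abs(recovered("sc_score") - recovered("ours")) < 0.02
    assert np.corrcoef(obs["sc_score"], obs["ours"])[0, 1] > 0.9


# -------------------------------------------------------------- group tests


def test_compare_patient_scores_detects_planted_shift():
    cfg = ExprSimConfig(n_patients=12, module_shift=0.5, seed=13)
    cm, _ = simulate_expression_cohort(cfg)
    tab = score_gene_module(log_normalize(cm), APRIL_MODULE, seed=0)
    res = compare_patient_scores(tab, ("SMM", "HD"), timepoint="post")
    assert res.p < 0.01
    assert res.effect_r > 0.8  # SMM (shifted up) dominates


def test_pergene_test_recovers_planted_genes():
    """With a subset of module genes shifted, per-gene BH recovers them."""
    rng = np.random.Generator(np.random.PCG64(4))
    n_per_group = 150
    genes = APRIL_MODULE + [f"g{i}" for i in range(100)]
    vals = rng.normal(1.0, 0.3, size=(2 * n_per_group, len(genes))).clip(min=0)
    planted = APRIL_MODULE[:8]
    for g in planted:
        vals[n_per_group:, genes.index(g)] -= 0.4  # down in group 2 (SMM)
    meta = pd.DataFrame({
        "individual_id": [f"p{i//15}" for i in range(2 * n_per_group)],
        "group": ["HD"] * n_per_group + ["SMM"] * n_per_group,
        "timepoint": ["post"] * 2 * n_per_group,
        "cell_type": ["B"] * 2 * n_per_group,
    })
    cm = _toy_matrix(vals, genes, meta)
    out = pergene_group_test(cm, APRIL_MODULE, ("HD", "SMM"))
    hits = set(out[out["q"] < 0.05]["gene"])
    assert len(hits & set(planted)) >= 7
    assert (out[out["gene"].isin(planted)]["direction"] > 0).all()  # HD higher


# --------------------------------------------------------------- validations


def _timecourse_frame(shift_genes, n_donors=4, noise=0.05, shift=1.0, seed=0):
    """Synthetic stand-in for a paired stimulation time course: VST-like
    values for 4 donors at baseline and one response timepoint."""
    rng = np.random.Generator(np.random.PCG64(seed))
    genes = APRIL_MODULE
    donor_base = {f"d{d}": rng.normal(8.0, 0.5, size=len(genes)) for d in range(n_donors)}
    samples, design_rows, rows = [], [], []
    for tp in (0, 120):
        for d in range(n_donors):
            sid = f"d{d}_t{tp}"
            samples.append(sid)
            design_rows.append({"sample": sid, "donor": f"d{d}", "timepoint": tp})
            vals = donor_base[f"d{d}"] + noise * rng.normal(size=len(genes))
            if tp == 120:
                for g in shift_genes:
                    vals[genes.index(g)] += shift
            rows.append(vals)
    expr = pd.DataFrame(rows, index=samples, columns=genes)
    design = pd.DataFrame(design_rows).set_index("sample")
    return expr, design


def test_validate_timecourse_calls_exactly_planted_genes():
    shifted = APRIL_MODULE[:12]
    expr, design = _timecourse_frame(shifted, seed=5)
    out = validate_timecourse(expr, design, APRIL_MODULE, baseline_timepoint=0)
    called = set(out[out["significant_up"]]["gene"])
    assert called == set(shifted)


def test_validate_timecourse_allflat_no_calls():
    expr, design = _timecourse_frame([], noise=0.0, seed=6)
    out = validate_timecourse(expr, design, APRIL_MODULE, baseline_timepoint=0)
    assert not out["significant_up"].any()


def test_validate_timecourse_paired_baseline_difference_noise_free():
    """Noise-free shifted genes have exactly the planted mean difference."""
    expr, design = _timecourse_frame(APRIL_MODULE[:3], noise=0.0, shift=1.0, seed=7)
    out = validate_timecourse(expr, design, APRIL_MODULE, baseline_timepoint=0)
    shifted = out[out["gene"].isin(APRIL_MODULE[:3])]
    assert shifted["mean_diff"].to_numpy() == pytest.approx([1.0] * 3)


def test_validate_external_plasma_cells_detects_direction():
    """Synthetic 9 vs 12 sample design with a planted SMM-down module shift."""
    cfg = ExprSimConfig(
        groups=("NBM", "SMM"), timepoints=("post",),
        n_patients={"NBM": 9, "SMM": 12}, n_cells_per_patient=60,
        module_shift=-0.4, shift_group="SMM", shift_timepoint="post",
        cell_type="plasma", seed=21,
    )
    cm, _ = simulate_expression_cohort(cfg)
    res, pergene = validate_external_plasma_cells(cm, APRIL_MODULE)
    assert res.p < 0.05
    assert res.effect_r > 0  # NBM (group 1) above SMM
    conc = concordance_table(pergene, pergene)
    assert conc["concordant"].all()


# ------------------------------------------------------- broad signatures


def test_signature_across_cell_types_and_paired_test():
    cfg = ExprSimConfig(
        groups=("HD",), n_patients=6, n_cells_per_patient=20, n_genes=400,
        module_shift=0.6, shift_group="HD", shift_timepoint="post", seed=17,
    )
    cm, _ = simulate_expression_cohort(cfg)
    norm = log_normalize(cm)
    pp = score_signature_across_cell_types(norm, APRIL_MODULE)
    assert set(pp.columns) >= {"individual_id", "timepoint", "score"}
    res = paired_signature_test(pp, "HD")
    assert res.p < 0.05
    assert res.effect_r > 0.9  # post above pre for every patient
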