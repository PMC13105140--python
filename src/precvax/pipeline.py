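"""End-to-end orchestration: simulate the enabled modalities, run each
analysis stage in dependency order, and write a machine-readable results
bundle plus a run manifest.

The run is configured by a :class:`RunConfig` (YAML-serializable).  All
statistical parameters and every generator default are echoed into the
manifest so each run is auditable; identical (config, seed) pairs produce
identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import write_json
from .proteomics import burden_correlation, cross_group_panel, paired_response_panel
from .serology import (
    cross_sectional_compare,
    eligible_for_kinetics,
    fit_waning_lmm,
    lrt_slope_heterogeneity,
    window_filter,
)
from .scoring import compare_patient_scores, log_normalize, pergene_group_test, score_gene_module
from .synth import (
    ExprSimConfig,
    NpxSimConfig,
    RepertoireSimConfig,
    TiterSimConfig,
    make_reference_lists,
    simulate_expression_cohort,
    simulate_npx_cohort,
    simulate_repertoire_cohort,
    simulate_titer_cohort,
)
from .tcr import (
    ClusteringParams,
    build_reference_panel,
    compare_pre_post,
    estimate_specific_proportion,
    harmonize_clonotypes,
)

logger = logging.getLogger(__name__)

STAGES = ("serology", "tcr", "scoring", "olink")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    stages: tuple[str, ...] = STAGES
    titer: dict = field(default_factory=dict)
    repertoire: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    npx: dict = field(default_factory=dict)
    n_subsample: int = 100
    n_iterations: int = 10
    exact_max_n: int = 8
    npx_family_mode: str = "per_protein_across_groups"
    windows: tuple[tuple[int, int], ...] = ((14, 60), (61, 120))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "windows" in raw:
            raw["windows"] = tuple(tuple(w) for w in raw["windows"])
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.npx_family_mode not in (
            "per_protein_across_groups", "per_group_across_proteins"
        ):
            raise ValueError(f"invalid npx_family_mode {self.npx_family_mode!r}")


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(_stringify_keys(asdict(cfg)), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_serology(cfg: RunConfig) -> dict:
    tcfg = TiterSimConfig(**cfg.titer, seed=cfg.seed)
    titers, truth = simulate_titer_cohort(tcfg)
    out: dict = {"truth": truth, "windows": {}}
    for window in cfg.windows:
        panel = window_filter(titers, window)
        if panel["group"].nunique() >= 2 and "HD" in set(panel["group"]):
            comp = cross_sectional_compare(panel, exact_max_n=cfg.exact_max_n)
            out["windows"][f"{window[0]}-{window[1]}"] = {
                g: r.to_dict() for g, r in comp.items()
            }
    eligible = eligible_for_kinetics(titers, groups=tcfg.groups)
    fit = fit_waning_lmm(eligible, "group_specific", groups=tcfg.groups)
    lrt = lrt_slope_heterogeneity(eligible, groups=tcfg.groups)
    out["waning_fit"] = fit.to_dict()
    out["lrt"] = lrt.to_dict()
    return out


def _stage_tcr(cfg: RunConfig) -> dict:
    refs = make_reference_lists(seed=cfg.seed + 101)
    params = ClusteringParams(seed=cfg.seed)
    panel = build_reference_panel(refs["spike"], refs["cef"], params)
    rcfg = RepertoireSimConfig(**cfg.repertoire, seed=cfg.seed + 1)
    records, truth = simulate_repertoire_cohort(rcfg, refs)
    reps = harmonize_clonotypes(records)
    group_of = dict(records.groupby("individual_id")["group"].first())
    estimates = [
        estimate_specific_proportion(
            rep, panel, n_subsample=cfg.n_subsample,
            n_iterations=cfg.n_iterations, seed=cfg.seed + 7 + i, params=params,
        )
        for i, rep in enumerate(reps.values())
    ]
    out = {
        "truth_config": truth["config"],
        "panel": {
            "n_spike_clusters": panel.n_clusters("spike"),
            "n_cef_clusters": panel.n_clusters("cef"),
            "discarded_mixed": panel.discarded_mixed,
        },
        "estimates": [e.to_dict() for e in estimates],
    }
    for antigen in ("spike", "cef"):
        comp = compare_pre_post(estimates, group_of, antigen, exact_max_n=cfg.exact_max_n)
        out[f"pre_post_{antigen}"] = {g: r.to_dict() for g, r in comp.items()}
    return out


def _stage_scoring(cfg: RunConfig) -> dict:
    ecfg = ExprSimConfig(**cfg.expression, seed=cfg.seed + 2)
    cm, truth = simulate_expression_cohort(ecfg)
    norm = log_normalize(cm)
    table = score_gene_module(norm, ecfg.module_genes, seed=cfg.seed)
    comp = compare_patient_scores(
        table, groups=ecfg.groups[:2], timepoint=ecfg.shift_timepoint,
        exact_max_n=cfg.exact_max_n,
    )
    pergene = pergene_group_test(
        norm, ecfg.module_genes, groups=ecfg.groups[:2], timepoint=ecfg.shift_timepoint
    )
    return {
        "truth": truth,
        "patient_level_test": comp.to_dict(),
        "pergene": pergene.to_dict(orient="records"),
    }


def _stage_olink(cfg: RunConfig) -> dict:
    ncfg = NpxSimConfig(**cfg.npx, seed=cfg.seed + 3)
    npx, burden, truth = simulate_npx_cohort(ncfg)
    paired = paired_response_panel(npx, family_mode=cfg.npx_family_mode,
                                   exact_max_n=cfg.exact_max_n)
    cross = {
        tp: cross_group_panel(npx, tp, exact_max_n=cfg.exact_max_n).to_dict(orient="records")
        for tp in ("pre", "post")
    }
    out = {
        "truth": truth,
        "paired_panel": paired.to_dict(orient="records"),
        "cross_group": cross,
    }
    if not burden.empty:
        corr, scatter = burden_correlation(
            npx, burden.set_index("individual_id")["m_spike"],
            protein=ncfg.april_protein,
        )
        out["burden_correlation"] = corr.to_dict()
        out["burden_scatter"] = scatter.to_dict(orient="records")
    return out


_STAGE_FN = {
    "serology": _stage_serology,
    "tcr": _stage_tcr,
    "scoring": _stage_scoring,
    "olink": _stage_olink,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages end to end; returns and writes the bundle.

    Fails fast on configuration errors before any stage runs.  Writes
    ``bundle.json`` and ``manifest.json`` under ``cfg.outdir``.
    """
    cfg.validate()
    for stage in cfg.stages:  # pre-flight: build stage configs before running
        if stage == "serology":
            TiterSimConfig(**cfg.titer, seed=cfg.seed)
        elif stage == "tcr":
            RepertoireSimConfig(**cfg.repertoire, seed=cfg.seed)
        elif stage == "scoring":
            ExprSimConfig(**cfg.expression, seed=cfg.seed)
        elif stage == "olink":
            NpxSimConfig(**cfg.npx, seed=cfg.seed)
    bundle: dict = {"stages": {}}
    for stage in cfg.stages:
        logger.info("running stage %s", stage)
        try:
            bundle["stages"][stage] = _STAGE_FN[stage](cfg)
        except Exception as exc:  # stage failure is recorded, not fatal
            logger.exception("stage %s failed", stage)
            bundle["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
    manifest = {
        "config": _stringify_keys(asdict(cfg)),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
    }
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(bundle, outdir / "bundle.json")
    write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def make_report(bundle: dict) -> str:
    """Render a deterministic human-readable summary of a results bundle."""
    lines: list[str] = ["# Pipeline report", ""]
    stages = bundle.get("stages", {})
    if not stages:
        logger.warning("empty bundle: nothing to report")
        return "# Pipeline report\n\n(no stages were run)\n"
    for stage in STAGES:
        if stage not in stages:
            continue
        data = stages[stage]
        lines.append(f"## {stage}")
        if "error" in data:
            lines.append(f"FAILED: {data['error']}")
            lines.append("")
            continue
        if stage == "serology":
            fit = data["waning_fit"]
            for g in sorted(fit["slope_per_group"]):
                lines.append(f"- {g} waning slope: {fit['slope_per_group'][g]:+.5f} log-titer/day")
            lrt = data["lrt"]
            lines.append(
                f"- LRT slope heterogeneity: stat={lrt['stat']:.3f}, "
                f"df={lrt['df']}, p={lrt['p']:.4f}"
            )
        elif stage == "tcr":
            for antigen in ("spike", "cef"):
                for g, r in sorted(data[f"pre_post_{antigen}"].items()):
                    lines.append(
                        f"- {antigen} pre/post {g}: p={r['p']:.4f}, r={r['effect_r']:+.2f}"
                    )
        elif stage == "scoring":
            t = data["patient_level_test"]
            lines.append(
                f"- module score patient-level test: p={t['p']:.4f}, r={t['effect_r']:+.2f}"
            )
            n_sig = sum(1 for r in data["pergene"] if r["q"] < 0.05)
            lines.append(f"- per-gene tests at q<0.05: {n_sig}/{len(data['pergene'])}")
        elif stage == "olink":
            sig = [r for r in data["paired_panel"] if r["q"] < 0.05]
            lines.append(f"- paired responses at q<0.05: {len(sig)}")
            if "burden_correlation" in data:
                c = data["burden_correlation"]
                lines.append(
                    f"- APRIL vs tumor burden: rho={c['rho']:+.3f}, p={c['p']:.2e}, n={c['n']}"
                )
        lines.append("")
    return "\n".join(lines)
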