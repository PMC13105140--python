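"""Synthetic cohort generators with planted, recoverable ground truth.

Four modalities mirror the statistical structure the downstream analyses
consume:

* longitudinal antibody titers — log-linear decay with patient random
  intercepts and group-specific slopes;
* CDR3beta repertoires — random background sequences plus planted
  antigen-specific clones copied (or single-substitution mutated) from
  labeled reference lists, expanding post-vaccination only where configured;
* cell x gene count matrices — negative-binomial counts with an additive
  module-expression shift (on the log-normalized scale) planted in one
  (group, timepoint) stratum;
* paired NPX proteomics — pre/post values with group-graded vaccination
  shifts and an APRIL analyte generated monotone-decreasing in a
  tumor-burden covariate.

Every generator is bit-reproducible given (config, seed): a single seed
sequence is spawned into per-individual substreams, and each truth record
echoes the planted effects exactly as configured.  The generators target
only the statistical structure the pipeline tests — no attempt is made to
mimic full assay realism (batch effects, doublets, ambient RNA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .io import AA_ALPHABET, CellMatrix

logger = logging.getLogger(__name__)

#: APRIL-responsive gene module: NF-kB pathway components, pro-survival
#: factors, adhesion molecules, and immunomodulatory mediators downstream of
#: APRIL-BCMA signaling.
APRIL_MODULE = [
    "NFKB1", "NFKB2", "RELB", "NFKBIA",
    "MCL1", "BCL2",
    "CD44", "ICAM1",
    "CCL3", "CCL4", "VEGFA", "IL10", "CD274", "TGFB1", "CXCL8",
]

#: The 52-analyte inflammation panel measured in the proteomics arm.
OLINK_PANEL = [
    "CCL2", "CCL3", "CCL4", "CCL7", "CCL8", "CCL11", "CCL13", "CCL19",
    "CCL20", "CLEC4A", "CSF1", "CSF3", "CXCL5", "CXCL6", "CXCL8", "CXCL9",
    "CXCL10", "CXCL11", "CXCL12", "DDX58", "EGF", "FLT3LG", "GZMB", "HGF",
    "IFNG", "IL1B", "IL6", "IL7", "IL10", "IL15", "IL17C", "IL18", "IL27",
    "IL4R", "IL5RA", "ITGB6", "LAG3", "LTA", "MMP1", "MMP7", "MMP12",
    "NUB1", "OLR1", "OSM", "TGFA", "TNF", "TNFRSF11A", "TNFSF10",
    "TNFSF12", "TNFSF13", "TNFSF14", "VEGFA",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


def _per_group(value, groups, name: str) -> dict:
    """Broadcast a scalar to all groups, or validate a per-group mapping."""
    if isinstance(value, Mapping):
        missing = [g for g in groups if g not in value]
        if missing:
            raise ConfigError(f"{name} missing groups {missing}")
        return {g: value[g] for g in groups}
    return {g: value for g in groups}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


# ===================================================================== titers


@dataclass
class TiterSimConfig:
    """Generating parameters of the log-linear antibody-waning model.

    ``log_titer = intercept_g + u_i + slope_g * day + eps`` with
    ``u_i ~ N(0, sigma_intercept^2)`` and ``eps ~ N(0, sigma_resid^2)``.
    Sampling days are uniform integers within ``day_range`` per patient (the
    real visit schedule is irregular; uniform sampling is the simplest
    faithful stand-in).
    """

    groups: tuple[str, ...] = ("MGUS", "SMM")
    n_per_group: int | Mapping[str, int] = 200
    slope_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"MGUS": -0.0043, "SMM": -0.0085}
    )
    intercept_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"MGUS": 8.0, "SMM": 8.0}
    )
    sigma_intercept: float = 0.5
    sigma_resid: float = 0.15
    samples_per_patient: int = 3
    day_range: tuple[int, int] = (14, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        n = _per_group(self.n_per_group, self.groups, "n_per_group")
        if min(n.values()) < 2:
            raise ConfigError("need at least 2 individuals per group")
        if self.sigma_intercept < 0 or self.sigma_resid < 0:
            raise ConfigError("variance components must be nonnegative")
        if not self.day_range[0] < self.day_range[1]:
            raise ConfigError(f"invalid day range {self.day_range}")
        if self.samples_per_patient < 1:
            raise ConfigError("samples_per_patient must be >= 1")


def simulate_titer_cohort(cfg: TiterSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a longitudinal titer cohort; returns (table, truth record).

    The table has one row per (individual, day) with columns
    ``individual_id, group, days_post_dose2, titer, log_titer`` (natural-log
    titers; ``titer = exp(log_titer)``).
    """
    n_map = _per_group(cfg.n_per_group, cfg.groups, "n_per_group")
    slopes = _per_group(cfg.slope_per_group, cfg.groups, "slope_per_group")
    intercepts = _per_group(cfg.intercept_per_group, cfg.groups, "intercept_per_group")
    total = sum(n_map.values())
    rngs = iter(_spawn(cfg.seed, total))
    rows = []
    lo, hi = cfg.day_range
    for group in cfg.groups:
        for k in range(n_map[group]):
            rng = next(rngs)
            ind = f"{group}_{k:04d}"
            u = rng.normal(0.0, cfg.sigma_intercept) if cfg.sigma_intercept > 0 else 0.0
            days = np.sort(rng.integers(lo, hi + 1, size=cfg.samples_per_patient))
            eps = (
                rng.normal(0.0, cfg.sigma_resid, size=cfg.samples_per_patient)
                if cfg.sigma_resid > 0
                else np.zeros(cfg.samples_per_patient)
            )
            log_t = intercepts[group] + u + slopes[group] * days + eps
            for d, lt in zip(days, log_t):
                rows.append((ind, group, int(d), math.exp(lt), float(lt)))
    df = pd.DataFrame(
        rows, columns=["individual_id", "group", "days_post_dose2", "titer", "log_titer"]
    )
    df["dose"] = 2
    truth = {
        "slope_per_group": dict(slopes),
        "intercept_per_group": dict(intercepts),
        "sigma_intercept": cfg.sigma_intercept,
        "sigma_resid": cfg.sigma_resid,
        "n_per_group": dict(n_map),
        "samples_per_patient": cfg.samples_per_patient,
        "day_range": list(cfg.day_range),
        "seed": cfg.seed,
    }
    return df, truth


# ================================================================ repertoires


@dataclass
class RepertoireSimConfig:
    """Planted-clone repertoire generator configuration.

    Planted antigen-specific clonotypes are copies or single-substitution
    variants of reference sequences; background sequences are uniform random
    amino-acid strings rejected whenever they fall within Hamming distance 1
    of any reference, so the planted fraction is exact ground truth.
    """

    groups: tuple[str, ...] = ("HD", "MGUS", "SMM")
    n_individuals: int | Mapping[str, int] = 12
    clonotypes_per_sample: int = 300
    planted_spike_pre: float | Mapping[str, float] = 0.02
    planted_spike_post: float | Mapping[str, float] = 0.02
    planted_cef: float | Mapping[str, float] = 0.05
    mutation_rate: float = 0.5
    background_length_range: tuple[int, int] = (10, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_spike_pre", "planted_spike_post", "planted_cef"):
            fr = _per_group(getattr(self, name), self.groups, name)
            if any(not 0.0 <= f <= 1.0 for f in fr.values()):
                raise ConfigError(f"{name} fractions must lie in [0, 1]")
        if self.clonotypes_per_sample < 1:
            raise ConfigError("clonotypes_per_sample must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ConfigError("mutation_rate must lie in [0, 1]")
        lo, hi = self.background_length_range
        if lo < 5 or hi < lo:
            raise ConfigError("invalid background_length_range")


def _masked_keys(seq: str):
    yield seq
    for i in range(len(seq)):
        yield f"{seq[:i]}*{seq[i + 1:]}"


def hamming1_reject_set(sequences: Sequence[str]) -> set[str]:
    """Keys covering every sequence within Hamming distance <= 1 of the input."""
    keys: set[str] = set()
    for s in sequences:
        keys.update(_masked_keys(s))
    return keys


def _collides(seq: str, reject: set[str]) -> bool:
    return any(k in reject for k in _masked_keys(seq))


def _random_cdr3(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    idx = rng.integers(0, len(AA_ALPHABET), size=length)
    return "".join(AA_ALPHABET[i] for i in idx)


def _mutate_once(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(0, len(seq)))
    choices = [a for a in AA_ALPHABET if a != seq[pos]]
    return seq[:pos] + choices[int(rng.integers(0, len(choices)))] + seq[pos + 1:]


def make_reference_lists(
    n_spike_families: int = 12,
    n_cef_families: int = 12,
    family_size: int = 4,
    length_range: tuple[int, int] = (12, 16),
    min_separation: int = 5,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Generate well-separated synthetic antigen reference CDR3 lists.

    Each family is a star of single-substitution variants around a random
    centroid; centroids of equal length are kept at least ``min_separation``
    substitutions apart so families (and labels) never bridge under a
    Hamming-1 clustering radius.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    centroids: list[str] = []
    while len(centroids) < n_spike_families + n_cef_families:
        cand = _random_cdr3(rng, length_range)
        ok = all(
            len(c) != len(cand) or sum(a != b for a, b in zip(c, cand)) >= min_separation
            for c in centroids
        )
        if ok:
            centroids.append(cand)

    def family(centroid: str) -> list[str]:
        members = {centroid}
        while len(members) < family_size:
            members.add(_mutate_once(rng, centroid))
        return sorted(members)

    spike = [s for c in centroids[:n_spike_families] for s in family(c)]
    cef = [s for c in centroids[n_spike_families:] for s in family(c)]
    return {"spike": spike, "cef": cef}


def simulate_repertoire_cohort(
    cfg: RepertoireSimConfig, panel_source: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-individual pre/post repertoires with planted clones.

    Returns a clonotype table (``individual_id, group, timepoint, cdr3_aa,
    duplicate_count, planted_label``) and a truth record with the planted
    fraction and identity of every planted clonotype.
    """
    for label in ("spike", "cef"):
        if not panel_source.get(label):
            raise ConfigError(f"panel_source must contain sequences for {label!r}")
    reject_all = hamming1_reject_set(
        [s for seqs in panel_source.values() for s in seqs]
    )
    reject_by_label = {lab: hamming1_reject_set(seqs) for lab, seqs in panel_source.items()}
    n_map = _per_group(cfg.n_individuals, cfg.groups, "n_individuals")
    spike_pre = _per_group(cfg.planted_spike_pre, cfg.groups, "planted_spike_pre")
    spike_post = _per_group(cfg.planted_spike_post, cfg.groups, "planted_spike_post")
    cef_frac = _per_group(cfg.planted_cef, cfg.groups, "planted_cef")

    rngs = iter(_spawn(cfg.seed, sum(n_map.values())))
    rows = []
    truth_samples = []
    other_label = {"spike": "cef", "cef": "spike"}
    for group in cfg.groups:
        for k in range(n_map[group]):
            rng = next(rngs)
            ind = f"{group}_{k:04d}"
            for timepoint, sp_frac in (("pre", spike_pre[group]), ("post", spike_post[group])):
                target = {"spike": sp_frac, "cef": cef_frac[group]}
                repertoire: set[str] = set()
                planted: dict[str, list[str]] = {"spike": [], "cef": []}
                for lab in ("spike", "cef"):
                    n_plant = round(target[lab] * cfg.clonotypes_per_sample)
                    if target[lab] > 0 and n_plant == 0:
                        logger.warning(
                            "%s %s: planted %s fraction %.4g rounds to zero clones",
                            ind, timepoint, lab, target[lab],
                        )
                    refs = list(panel_source[lab])
                    while len(planted[lab]) < n_plant:
                        base = refs[int(rng.integers(0, len(refs)))]
                        seq = base
                        if cfg.mutation_rate > 0 and rng.random() < cfg.mutation_rate:
                            seq = _mutate_once(rng, seq)
                        # keep planted clones unique and strictly single-label
                        if seq in repertoire or _collides(seq, reject_by_label[other_label[lab]]):
                            continue
                        repertoire.add(seq)
                        planted[lab].append(seq)
                n_background = cfg.clonotypes_per_sample - len(repertoire)
                while n_background > 0:
                    seq = _random_cdr3(rng, cfg.background_length_range)
                    if seq in repertoire or _collides(seq, reject_all):
                        continue
                    repertoire.add(seq)
                    n_background -= 1
                planted_lookup = {s: lab for lab in planted for s in planted[lab]}
                for seq in sorted(repertoire):
                    rows.append(
                        (ind, group, timepoint, seq, 1, planted_lookup.get(seq, ""))
                    )
                truth_samples.append(
                    {
                        "individual_id": ind,
                        "group": group,
                        "timepoint": timepoint,
                        "planted_spike_fraction": len(planted["spike"])
                        / cfg.clonotypes_per_sample,
                        "planted_cef_fraction": len(planted["cef"])
                        / cfg.clonotypes_per_sample,
                        "planted_spike": planted["spike"],
                        "planted_cef": planted["cef"],
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "group", "timepoint", "cdr3_aa", "duplicate_count",
                 "planted_label"],
    )
    truth = {
        "config": {
            "planted_spike_pre": dict(spike_pre),
            "planted_spike_post": dict(spike_post),
            "planted_cef": dict(cef_frac),
            "clonotypes_per_sample": cfg.clonotypes_per_sample,
            "mutation_rate": cfg.mutation_rate,
            "seed": cfg.seed,
        },
        "samples": truth_samples,
    }
    return df, truth


# ================================================================= expression


@dataclass
class ExprSimConfig:
    """Negative-binomial count-matrix generator with a planted module shift.

    Per-gene count means are drawn log-normal (creating the expression strata
    that control-gene binning needs); module-gene means are boosted so that
    planted log-scale shifts are representable in integer counts.  The shift
    is planted by passing module-gene counts of the designated stratum
    through the log1p-normalization, adding ``module_shift``, and inverting
    (rounded back to integer counts) — hence recovered score differences
    carry rounding/sampling noise.
    """

    groups: tuple[str, ...] = ("HD", "SMM")
    timepoints: tuple[str, ...] = ("pre", "post")
    n_patients: int | Mapping[str, int] = 18
    n_cells_per_patient: int = 40
    n_genes: int = 1000
    gene_names: Sequence[str] | None = None
    module_genes: Sequence[str] = field(default_factory=lambda: list(APRIL_MODULE))
    module_shift: float = 0.0
    shift_group: str = "SMM"
    shift_timepoint: str = "post"
    cell_type: str = "B"
    nb_mean_log_mu: float = 0.5
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.5
    module_mean_boost: float = 8.0
    target_sum: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        names = self.resolved_gene_names()
        if len(names) != self.n_genes:
            raise ConfigError("gene_names length must equal n_genes")
        missing = set(self.module_genes) - set(names)
        if missing:
            raise ConfigError(f"module genes not in gene universe: {sorted(missing)}")
        if self.n_genes < len(self.module_genes) + 50:
            raise ConfigError("n_genes too small for module plus control pool")

    def resolved_gene_names(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        fillers = [f"G{i:05d}" for i in range(self.n_genes - len(self.module_genes))]
        return list(self.module_genes) + fillers


def simulate_expression_cohort(cfg: ExprSimConfig) -> tuple[CellMatrix, dict]:
    """Simulate a cell x gene count cohort; returns (CellMatrix, truth)."""
    gene_names = cfg.resolved_gene_names()
    n_map = _per_group(cfg.n_patients, cfg.groups, "n_patients")
    master = np.random.Generator(np.random.PCG64(np.random.SeedSequence(cfg.seed)))
    means = np.exp(master.normal(cfg.nb_mean_log_mu, cfg.nb_mean_log_sigma, size=cfg.n_genes))
    mod_idx = np.array([gene_names.index(g) for g in cfg.module_genes], dtype=int)
    means[mod_idx] *= cfg.module_mean_boost
    nb_n = 1.0 / cfg.nb_dispersion
    nb_p = nb_n / (nb_n + means)

    rngs = iter(_spawn(cfg.seed + 1, sum(n_map.values())))
    blocks, meta_rows = [], []
    for group in cfg.groups:
        for k in range(n_map[group]):
            rng = next(rngs)
            ind = f"{group}_{k:04d}"
            for timepoint in cfg.timepoints:
                counts = rng.negative_binomial(
                    nb_n, nb_p, size=(cfg.n_cells_per_patient, cfg.n_genes)
                ).astype(np.int64)
                if (
                    cfg.module_shift != 0.0
                    and group == cfg.shift_group
                    and timepoint == cfg.shift_timepoint
                ):
                    totals = counts.sum(axis=1, keepdims=True).astype(float)
                    totals[totals == 0] = 1.0
                    sf = cfg.target_sum / totals
                    sub = counts[:, mod_idx].astype(float)
                    target = np.log1p(sub * sf) + cfg.module_shift
                    # stochastic rounding in log space: pick between the two
                    # bracketing integer counts with the interpolation weight,
                    # so E[log1p(count*sf)] equals the target exactly and the
                    # planted shift carries no quantization bias
                    k0 = np.floor(np.expm1(target) / sf)
                    k0 = np.maximum(k0, 0.0)
                    lo = np.log1p(k0 * sf)
                    k0 = np.where(lo > target, np.maximum(k0 - 1, 0.0), k0)
                    lo = np.log1p(k0 * sf)
                    hi = np.log1p((k0 + 1) * sf)
                    frac = np.clip((target - lo) / (hi - lo), 0.0, 1.0)
                    bump = rng.random(size=sub.shape) < frac
                    counts[:, mod_idx] = (k0 + bump).astype(np.int64)
                blocks.append(sparse.csr_matrix(counts))
                for c in range(cfg.n_cells_per_patient):
                    meta_rows.append((f"{ind}_{timepoint}_{c:04d}", ind, group,
                                      timepoint, cfg.cell_type))
    X = sparse.vstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "individual_id", "group", "timepoint", "cell_type"]
    )
    cm = CellMatrix(X=X, gene_names=gene_names, cell_meta=meta)
    truth = {
        "module_genes": list(cfg.module_genes),
        "module_shift": cfg.module_shift,
        "shift_group": cfg.shift_group,
        "shift_timepoint": cfg.shift_timepoint,
        "n_patients": dict(n_map),
        "n_cells_per_patient": cfg.n_cells_per_patient,
        "nb_dispersion": cfg.nb_dispersion,
        "seed": cfg.seed,
    }
    return cm, truth


# ======================================================================= NPX


@dataclass
class NpxSimConfig:
    """Paired-NPX generator with group-graded shifts and an APRIL-burden link.

    Each individual gets a protein-level random offset shared by both
    timepoints (so paired tests see only the planted shift plus residual
    noise).  For individuals of ``burden_group``, the APRIL analyte is
    generated as a monotone decreasing function of a tumor-burden covariate
    (M-spike, g/dL) plus noise.
    """

    proteins: Sequence[str] = field(default_factory=lambda: list(OLINK_PANEL))
    groups: tuple[str, ...] = ("HD", "MGUS", "SMM")
    n_per_group: int | Mapping[str, int] = field(
        default_factory=lambda: {"HD": 13, "MGUS": 14, "SMM": 18}
    )
    baseline_npx: float = 5.0
    sigma_individual: float = 1.0
    sigma_noise: float = 0.3
    paired_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    april_protein: str = "TNFSF13"
    burden_group: str = "SMM"
    burden_range: tuple[float, float] = (0.5, 3.0)
    april_link: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": 7.0, "slope": 1.0, "noise_sd": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0 or self.sigma_individual < 0:
            raise ConfigError("noise SDs must be nonnegative")
        if self.april_link.get("noise_sd", 0.0) < 0:
            raise ConfigError("april_link noise_sd must be nonnegative")
        for (prot, grp) in self.paired_shift:
            if prot not in self.proteins or grp not in self.groups:
                raise ConfigError(f"paired_shift key ({prot}, {grp}) outside panel/groups")


def simulate_npx_cohort(cfg: NpxSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate paired NPX records; returns (npx table, burden table, truth)."""
    n_map = _per_group(cfg.n_per_group, cfg.groups, "n_per_group")
    rngs = iter(_spawn(cfg.seed, sum(n_map.values())))
    rows, burden_rows = [], []
    link = cfg.april_link
    for group in cfg.groups:
        for k in range(n_map[group]):
            rng = next(rngs)
            ind = f"{group}_{k:04d}"
            burden = None
            if group == cfg.burden_group:
                burden = float(rng.uniform(*cfg.burden_range))
                burden_rows.append((ind, group, burden))
            offsets = rng.normal(0.0, cfg.sigma_individual, size=len(cfg.proteins))
            for j, prot in enumerate(cfg.proteins):
                if prot == cfg.april_protein and burden is not None:
                    base = link["intercept"] - link["slope"] * burden
                    noise_sd = link.get("noise_sd", 0.0)
                else:
                    base = cfg.baseline_npx + offsets[j]
                    noise_sd = cfg.sigma_noise
                shift = cfg.paired_shift.get((prot, group), 0.0)
                for timepoint, delta in (("pre", 0.0), ("post", shift)):
                    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append((prot, ind, group, timepoint, base + delta + eps))
    npx = pd.DataFrame(rows, columns=["protein", "individual_id", "group", "timepoint", "npx"])
    burden = pd.DataFrame(burden_rows, columns=["individual_id", "group", "m_spike"])
    truth = {
        "paired_shift": {f"{p}|{g}": s for (p, g), s in cfg.paired_shift.items()},
        "april_link": dict(link),
        "burden_group": cfg.burden_group,
        "n_per_group": dict(n_map),
        "seed": cfg.seed,
    }
    return npx, burden, truth
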