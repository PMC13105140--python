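"""CDR3beta clustering, antigen reference panels, and the bootstrapped
co-clustering estimator of antigen-specific clonotype proportions.

Clustering follows a two-step scheme: an optional coarse k-means partition
on fixed-length physicochemical profile vectors (engaged only for large
inputs), then, within each coarse block, a graph with an edge between two
sequences iff they have equal length and Hamming distance <= 1, on whose
connected components Markov clustering (expansion 2, inflation 2) is run.
Output clusters are therefore always subsets of the Hamming-<=1 connected
components, and equal them whenever MCL converges to the components.

Antigen specificity of a repertoire is estimated by repeatedly subsampling
unique clonotypes, co-clustering each subsample with a purity-filtered
reference panel of spike- and CEF-labeled CDR3 clusters, and averaging the
fraction of subsampled clonotypes that land in single-label reference
clusters.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import _CDR3_RE
from .stats import TestResult, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- repertoires


@dataclass
class Repertoire:
    """An individual x timepoint set of unique CDR3beta clonotypes."""

    individual_id: str
    timepoint: str
    clonotypes: tuple[str, ...]  # sorted, unique
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.clonotypes)) != len(self.clonotypes):
            raise ValueError("clonotypes must be unique")


def harmonize_clonotypes(records: pd.DataFrame) -> dict[tuple[str, str], Repertoire]:
    """Aggregate clonotype records into harmonized per-(individual, timepoint)
    repertoires.

    Clonotypes are redefined by exact CDR3 amino-acid identity: the same
    sequence observed in several samples or aliquots becomes one clonotype
    with summed counts.  Requires columns ``individual_id, timepoint,
    cdr3_aa`` (``duplicate_count`` defaults to 1).
    """
    df = records.copy()
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    if "junction_aa" in df.columns and "cdr3_aa" not in df.columns:
        df = df.rename(columns={"junction_aa": "cdr3_aa"})
    out: dict[tuple[str, str], Repertoire] = {}
    for (ind, tp), sub in df.groupby(["individual_id", "timepoint"], sort=True):
        counts = sub.groupby("cdr3_aa")["duplicate_count"].sum().to_dict()
        if not counts:
            logger.info("empty repertoire for %s/%s", ind, tp)
        out[(ind, tp)] = Repertoire(
            individual_id=str(ind),
            timepoint=str(tp),
            clonotypes=tuple(sorted(counts)),
            counts={k: int(v) for k, v in counts.items()},
        )
    return out


# ------------------------------------------------------------------ clustering


@dataclass
class ClusteringParams:
    """Hyperparameters of the two-step CDR3 clustering."""

    expansion: int = 2
    inflation: float = 2.0
    pruning: float = 1e-5
    max_iterations: int = 100
    coarse_threshold: int = 5000  # below this the exact graph is built directly
    coarse_block_size: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "expansion": self.expansion,
            "inflation": self.inflation,
            "pruning": self.pruning,
            "max_iterations": self.max_iterations,
            "coarse_threshold": self.coarse_threshold,
            "coarse_block_size": self.coarse_block_size,
            "seed": self.seed,
        }


@dataclass
class ClusterSet:
    """Disjoint CDR3 clusters covering the input sequences."""

    clusters: list[frozenset[str]]
    params: ClusteringParams

    def membership(self) -> dict[str, int]:
        return {s: i for i, c in enumerate(self.clusters) for s in c}


def hamming_edges(sequences: Sequence[str]) -> list[tuple[int, int]]:
    """Index pairs at Hamming distance exactly 1 (equal length required).

    Uses single-position wildcard hashing: two equal-length sequences are at
    Hamming distance 1 iff they share a masked key at exactly one position.
    """
    buckets: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(sequences):
        for pos in range(len(s)):
            buckets[f"{pos}|{s[:pos]}*{s[pos + 1:]}"].append(i)
    edges: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) > 1:
            for a, b in itertools.combinations(members, 2):
                edges.add((a, b) if a < b else (b, a))
    return sorted(edges)


def _markov_cluster(adj: np.ndarray, params: ClusteringParams) -> list[list[int]] | None:
    """MCL on a dense adjacency matrix; returns node clusters or None if the
    iteration did not converge within the budget."""
    n = adj.shape[0]
    M = adj.astype(float) + np.eye(n)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(params.max_iterations):
        prev = M
        for _e in range(params.expansion - 1):
            M = M @ M
        M = M ** params.inflation
        M[M < params.pruning] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < 1e-8:
            break
    else:
        return None
    # attractors are rows with nonzero diagonal; each attractor row defines a
    # cluster; nodes attracted to several attractors go to the first
    clusters: list[list[int]] = []
    assigned = np.full(n, -1)
    for i in range(n):
        if M[i, i] > 0:
            members = [j for j in np.nonzero(M[i] > 0)[0] if assigned[j] < 0]
            if members:
                for j in members:
                    assigned[j] = len(clusters)
                clusters.append(members)
    for j in np.nonzero(assigned < 0)[0]:  # unattracted stragglers
        assigned[j] = len(clusters)
        clusters.append([int(j)])
    return clusters


_HYDROPHOBICITY = {  # Kyte-Doolittle
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
_CHARGE = {a: 0.0 for a in _HYDROPHOBICITY} | {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
    "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
    "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
    "W": 227.8, "Y": 193.6,
}


def _physchem_profile(seq: str) -> np.ndarray:
    h = np.array([_HYDROPHOBICITY[a] for a in seq])
    c = np.array([_CHARGE[a] for a in seq])
    v = np.array([_VOLUME[a] for a in seq])
    return np.array(
        [len(seq), h.mean(), h.var(), c.mean(), c.var(), v.mean() / 100, v.var() / 1e4]
    )


def _coarse_blocks(sequences: list[str], params: ClusteringParams) -> list[list[int]]:
    from sklearn.cluster import KMeans

    feats = np.array([_physchem_profile(s) for s in sequences])
    k = max(2, int(np.ceil(len(sequences) / params.coarse_block_size)))
    labels = KMeans(n_clusters=k, n_init=3, random_state=params.seed).fit_predict(feats)
    blocks: dict[int, list[int]] = defaultdict(list)
    for i, lab in enumerate(labels):
        blocks[int(lab)].append(i)
    return [blocks[lab] for lab in sorted(blocks)]


def cluster_cdr3(
    sequences: Iterable[str], params: ClusteringParams | None = None
) -> ClusterSet:
    """Cluster unique CDR3 sequences by the two-step Hamming/MCL scheme."""
    params = params or ClusteringParams()
    seqs = list(sequences)
    if len(set(seqs)) != len(seqs):
        raise ValueError("input sequences must be unique")
    for s in seqs:
        if not _CDR3_RE.fullmatch(s):
            raise ValueError(f"invalid amino-acid sequence: {s!r}")
    if not seqs:
        return ClusterSet(clusters=[], params=params)

    if len(seqs) > params.coarse_threshold:
        blocks = _coarse_blocks(seqs, params)
    else:
        blocks = [list(range(len(seqs)))]

    clusters: list[frozenset[str]] = []
    for block in blocks:
        block_seqs = [seqs[i] for i in block]
        edges = hamming_edges(block_seqs)
        n = len(block_seqs)
        # union-find connected components of the Hamming-<=1 graph
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comp_members: dict[int, list[int]] = defaultdict(list)
        for i in range(n):
            comp_members[find(i)].append(i)
        comp_edges: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for a, b in edges:
            comp_edges[find(a)].append((a, b))
        for root, members in comp_members.items():
            if len(members) <= 2:
                clusters.append(frozenset(block_seqs[i] for i in members))
                continue
            local = {node: j for j, node in enumerate(members)}
            sub = np.zeros((len(members), len(members)))
            for a, b in comp_edges[root]:
                sub[local[a], local[b]] = 1.0
                sub[local[b], local[a]] = 1.0
            mcl = _markov_cluster(sub, params)
            if mcl is None:
                logger.warning(
                    "MCL did not converge on a %d-node component; "
                    "falling back to the connected component", len(members)
                )
                clusters.append(frozenset(block_seqs[i] for i in members))
            else:
                for grp in mcl:
                    clusters.append(frozenset(block_seqs[members[i]] for i in grp))
    return ClusterSet(clusters=clusters, params=params)


# ------------------------------------------------------------ reference panel


@dataclass
class ReferencePanel:
    """Purity-filtered, antigen-labeled CDR3 reference clusters."""

    clusters: list[tuple[str, frozenset[str]]]  # (label, members)
    discarded_mixed: int
    dropped_ambiguous: int  # identical sequence present under both labels
    source_counts: dict[str, int]
    params: ClusteringParams

    def sequences(self) -> set[str]:
        return {s for _, c in self.clusters for s in c}

    def label_of(self) -> dict[str, str]:
        return {s: lab for lab, c in self.clusters for s in c}

    def n_clusters(self, label: str) -> int:
        return sum(1 for lab, _ in self.clusters if lab == label)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "clusters": [{"label": lab, "members": sorted(c)} for lab, c in self.clusters],
            "discarded_mixed": self.discarded_mixed,
            "dropped_ambiguous": self.dropped_ambiguous,
            "source_counts": self.source_counts,
            "params": self.params.to_dict(),
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferencePanel":
        obj = json.loads(Path(path).read_text())
        return cls(
            clusters=[(c["label"], frozenset(c["members"])) for c in obj["clusters"]],
            discarded_mixed=obj["discarded_mixed"],
            dropped_ambiguous=obj["dropped_ambiguous"],
            source_counts=obj["source_counts"],
            params=ClusteringParams(**obj["params"]),
        )


def build_reference_panel(
    spike_seqs: Sequence[str],
    cef_seqs: Sequence[str],
    params: ClusteringParams | None = None,
) -> ReferencePanel:
    """Pool, cluster, and purity-filter labeled antigen-specific CDR3 lists.

    Clusters containing both labels are discarded as non-specific; a sequence
    present verbatim under both labels is excluded before clustering
    (counted, warned).
    """
    if not spike_seqs or not cef_seqs:
        raise ValueError("both spike and cef source lists must be non-empty")
    spike = set(spike_seqs)
    cef = set(cef_seqs)
    ambiguous = spike & cef
    if ambiguous:
        logger.warning("%d sequences appear under both labels; excluded", len(ambiguous))
        spike -= ambiguous
        cef -= ambiguous
    label = {s: "spike" for s in spike} | {s: "cef" for s in cef}
    cs = cluster_cdr3(sorted(label), params)
    kept: list[tuple[str, frozenset[str]]] = []
    discarded = 0
    for cluster in cs.clusters:
        labs = {label[s] for s in cluster}
        if len(labs) == 1:
            kept.append((labs.pop(), cluster))
        else:
            discarded += 1
    return ReferencePanel(
        clusters=kept,
        discarded_mixed=discarded,
        dropped_ambiguous=len(ambiguous),
        source_counts={"spike": len(spike), "cef": len(cef)},
        params=cs.params,
    )


# ---------------------------------------------------------- proportion estimator


@dataclass
class SpecificityEstimate:
    """Bootstrapped antigen-specific clonotype proportions for one sample."""

    individual_id: str
    timepoint: str
    prop_spike: float
    prop_cef: float
    per_iteration: list[tuple[float, float]]
    n_subsample: int
    n_iterations: int
    seed: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "timepoint": self.timepoint,
            "prop_spike": self.prop_spike,
            "prop_cef": self.prop_cef,
            "per_iteration": self.per_iteration,
            "n_subsample": self.n_subsample,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "flags": self.flags,
        }


def estimate_specific_proportion(
    rep: Repertoire,
    panel: ReferencePanel,
    n_subsample: int = 100,
    n_iterations: int = 10,
    seed: int = 0,
    params: ClusteringParams | None = None,
) -> SpecificityEstimate:
    """Estimate spike-/CEF-specific clonotype fractions by co-clustering.

    Per iteration, ``n_subsample`` unique clonotypes are drawn without
    replacement and co-clustered with the full panel; a query clonotype is
    called for an antigen iff its cluster contains at least one panel
    sequence of that label and none of the other (mixed co-clusters confer
    no call).  Fractions are averaged across iterations.
    """
    if not rep.clonotypes:
        raise ValueError("repertoire is empty")
    flags: list[str] = []
    panel_label = panel.label_of()
    panel_seqs = sorted(panel_label)
    for lab in ("spike", "cef"):
        if panel.n_clusters(lab) == 0:
            flags.append(f"empty_panel_label:{lab}")
    rng = np.random.Generator(np.random.PCG64(seed))
    pool = np.array(rep.clonotypes)
    whole = len(pool) <= n_subsample
    iters = 1 if whole else n_iterations
    if whole:
        flags.append("repertoire_smaller_than_subsample")
    per_iter: list[tuple[float, float]] = []
    for _ in range(iters):
        queries = pool if whole else rng.choice(pool, size=n_subsample, replace=False)
        union = sorted(set(queries) | set(panel_seqs))
        cs = cluster_cdr3(union, params)
        calls = {"spike": 0, "cef": 0}
        member_of = cs.membership()
        cluster_labels: list[set[str]] = [
            {panel_label[s] for s in c if s in panel_label} for c in cs.clusters
        ]
        for q in queries:
            labs = cluster_labels[member_of[q]]
            if labs == {"spike"}:
                calls["spike"] += 1
            elif labs == {"cef"}:
                calls["cef"] += 1
        nq = len(queries)
        per_iter.append((calls["spike"] / nq, calls["cef"] / nq))
    spike_frac = float(np.mean([a for a, _ in per_iter]))
    cef_frac = float(np.mean([b for _, b in per_iter]))
    if "empty_panel_label:spike" in flags:
        spike_frac = 0.0
    if "empty_panel_label:cef" in flags:
        cef_frac = 0.0
    return SpecificityEstimate(
        individual_id=rep.individual_id,
        timepoint=rep.timepoint,
        prop_spike=spike_frac,
        prop_cef=cef_frac,
        per_iteration=per_iter,
        n_subsample=n_subsample,
        n_iterations=iters,
        seed=seed,
        flags=flags,
    )


def compare_pre_post(
    estimates: Sequence[SpecificityEstimate],
    group_of: Mapping[str, str],
    antigen: str = "spike",
    exact_max_n: int = 8,
) -> dict[str, TestResult]:
    """Paired signed-rank tests of pre vs post antigen-specific proportions
    within each group.  Individuals missing a timepoint are excluded (logged).
    """
    attr = {"spike": "prop_spike", "cef": "prop_cef"}[antigen]
    by_ind: dict[str, dict[str, float]] = defaultdict(dict)
    for est in estimates:
        by_ind[est.individual_id][est.timepoint] = getattr(est, attr)
    pairs: dict[str, list[tuple[float, float]]] = defaultdict(list)
    for ind, tps in by_ind.items():
        if "pre" in tps and "post" in tps:
            pairs[group_of[ind]].append((tps["pre"], tps["post"]))
        else:
            logger.info("individual %s missing a timepoint; excluded from pairing", ind)
    results: dict[str, TestResult] = {}
    for group, pp in sorted(pairs.items()):
        pre = [a for a, _ in pp]
        post = [b for _, b in pp]
        results[group] = wilcoxon_signed_rank(pre, post, exact_max_n=exact_max_n)
    return results
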