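# Methods

This note documents the models and procedures implemented in `precvax`,
their assumptions, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Antibody-waning mixed model

For individual *i* in disease group *g(i)* sampled *d* days after the
second vaccine dose,

    log(titer)_ij = α_g(i) + β_g(i) · d_ij + u_i + ε_ij,
    u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²).

Titers are modelled on the natural-log scale by default (`read_titer_csv`
accepts `log_base=10`; slope magnitudes are base-dependent, so the base is
part of any quoted slope).  Estimation is by **maximum likelihood, not
REML**, because the slope-heterogeneity test compares fixed-effect
structures of nested models and REML likelihoods are not comparable across
fixed-effect parameterizations.  With a single random intercept the
covariance of each individual's block is σ_e²(I + λJ) with
λ = σ_u²/σ_e², whose inverse and determinant are analytic; the fixed
effects are profiled out by generalized least squares and σ_e² in closed
form, leaving a one-dimensional concentrated likelihood in log λ that is
optimized by bounded scalar minimization (tolerance 1e−8 on the
log-likelihood).  The λ = 0 boundary (no between-patient variance) is
evaluated explicitly; when it wins, the fit is flagged `singular_fit` and
degenerates to pooled regression.  The implementation agrees with
statsmodels `MixedLM(reml=False)` to ~1e−7 on slopes and log-likelihood
(cross-checked in the test suite, where statsmodels is the independent
reference, never the fitting engine).

The likelihood-ratio statistic for slope heterogeneity is
2·(ll_group-specific − ll_common), clipped at zero, referred to χ² with
(#groups − 1) degrees of freedom.  Under a common-slope generator at a
clinical cohort size (14 + 21 patients, 3 samples each) its rejection rate
at α = 0.05 is 5.5% over 500 replicates (test suite), i.e. the χ²
reference is adequate at this scale.

Eligibility and windowing conventions: longitudinal fits
use individuals with ≥ 2 samples in the closed window [14, 120] days,
restricted to the configured groups; cross-sectional panels use closed
windows ([14, 60], [61, 120]) keeping only each individual's earliest
in-window sample (same-day ties keep the first row in file order, with a
warning).  Cross-sectional comparisons are two-sided rank-sum tests of
each group against the healthy-donor reference, BH-corrected within the
panel, with rank-biserial effect sizes flagged for reporting at q < 0.1.

## CDR3β clustering and antigen-specificity estimation

Clonotypes are defined by exact CDR3β amino-acid identity and harmonized
across samples/aliquots per (individual, timepoint) with counts summed.
Clustering is a two-step scheme:

1. *Coarse stage* (engaged only above 5,000 sequences; below that the
   exact graph is built directly): k-means on 7-dimensional per-sequence
   profiles (length; mean/variance of Kyte–Doolittle hydrophobicity,
   charge, and residue volume), targeting blocks of ~2,000.  Any coarse
   partition is acceptable provided it never splits a Hamming-1 pair; the
   test suite constructs such cases and asserts coarse/exact equality
   rather than assuming it.
2. *Fine stage*: within each block, a graph with an edge iff two sequences
   have equal length and Hamming distance ≤ 1 (found by single-position
   wildcard hashing, O(n·L)); Markov clustering (expansion 2, inflation 2,
   pruning 1e−5, ≤ 100 iterations) runs on each connected component, with
   a fall-back to the whole component (warned) if MCL does not converge.

Output clusters are therefore always disjoint subsets of the Hamming≤1
connected components and cover them exactly — verified against a
brute-force pairwise-Hamming oracle on repertoires up to 2,000 sequences.

The reference panel pools labeled spike- and CEF-specific CDR3β lists,
clusters them, discards clusters containing both labels as non-specific
(counted), and excludes sequences appearing verbatim under both labels
before clustering.  Specificity of a repertoire is estimated by sampling
100 unique clonotypes without replacement, co-clustering them with the
full panel, calling a query for an antigen iff its cluster contains at
least one panel sequence of that label and none of the other (mixed
co-clusters confer no call, inheriting the panel's purity logic), and
averaging call fractions over 10 independent iterations.  If the
repertoire is smaller than the subsample the whole repertoire is used once
(co-clustering is then deterministic, so the iterations collapse to one,
flagged).  Under the collision-rejecting generator (below), a planted
fraction of 0.20 in 2,000-clonotype repertoires is recovered with mean
absolute error < 0.03 over 50 seeds, and a planted fraction of 0 is
recovered as exactly 0.

## Gene-module scoring

Counts are normalized to 10,000 per cell and log1p-transformed (all-zero
cells are an error).  The per-cell module score is the mean over module
genes minus the mean over a control pool: genes are ranked by average
expression over the cells being scored and split into `n_bins = 25`
equal-occupancy bins; for each module gene, `ctrl_per_gene = 50` control
genes are sampled seeded, without replacement, excluding module genes,
from its bin, and the union of samples forms the pool.  These defaults are
the common reference values for this scoring scheme; both are configurable
and logged.  Two deliberate consequences: (i) bins are computed on the
cell subset being scored, which changes values relative to whole-matrix
binning; (ii) when `ctrl_per_gene` exhausts every bin, scores become
seed-independent and equal mean(module) − mean(matched background), which
the tests exploit as a closed form.  The score is exactly linear: adding a
constant to every module gene of a cell raises that cell's score by that
constant.  scanpy's `score_genes` — an independent implementation of the
same idea with different binning details — recovers the same planted
shifts and serves as a cross-check in the tests.

Group inference uses patient-level mean scores (rank-sum tests), per-gene
cell-level rank-sum panels BH-corrected across module genes, and two
external-validation procedures: a paired per-donor time-course t-test
(BH within each timepoint's module family; significant = q < 0.05 with
positive mean difference; zero-variance differences are handled as the
degenerate limits p = 1 for no change, p = 0 for an exactly constant
shift, with a warning) and a sample-level two-group comparison after mean
aggregation, plus a gene-by-gene direction-of-effect concordance table.
Broad response signatures (e.g. an IL-1β response signature) are scored
per cell type, averaged per patient and then across cell types, and
compared pre/post by paired signed-rank tests restricted to paired
individuals.

## Proteomic panels

NPX values (log2-scale relative units) are taken as provided.  Paired
pre/post tests are two-sided signed-rank per (protein, group) on
individuals with both timepoints; rows with < 3 pairs are flagged
underpowered; all-zero differences yield p = 1 rather than an error.  Two
BH family conventions exist in practice and both are provided —
`per_protein_across_groups` (3 tests per cytokine; the default, matching
the per-cytokine reporting convention) and `per_group_across_proteins`
(across the whole panel); switching the family changes q but never p.
Cross-group panels run all pairwise group rank-sum tests per protein at
one timepoint in a single BH family (52 proteins × 3 pairs = 156 tests).
Effect sizes (rank-biserial) are always computed and flagged for
reporting at q < 0.1.  The burden correlation is Spearman's ρ between one
analyte and a per-individual covariate (M-spike, g/dL), requiring ≥ 3
complete pairs and erroring on constant input.

## Shared statistics

Rank tests use exact enumeration when the smaller sample (or the number of
nonzero differences) is ≤ `exact_max_n = 8` and the data are untied —
small enough that exactness matters for the smallest assay cohorts —
and the normal approximation with tie and continuity corrections
otherwise; exact and approximate p agree within 0.01 at n ≈ 8–10.
Zero paired differences are dropped with a logged count; all-zero
differences raise a degenerate-data error at the stats layer (callers
that have a defensible limiting value handle it explicitly, as noted
above).  Effect sizes: unpaired r = 2U₁/(n₁n₂) − 1 (r = +1 means group 1
stochastically dominates); paired r = (W⁺ − W⁻)/(W⁺ + W⁻).  Spearman uses
midranks with a t-approximation, switching to full permutation enumeration
for untied samples of n ≤ 9.  BH adjustment preserves input order, never
lowers a p-value, and is order-equivariant; note it is *not* idempotent on
its own output (a second application can only raise q-values), so q-values
are computed once per declared family.  ELISPOT-style ratio comparisons
average replicates per individual and replace a zero control mean with a
floor of 0.5 spots (half the minimum countable unit) with a warning, since
the zero-well case is otherwise undefined.

## Synthetic cohorts

The generators emulate only the statistical structure the pipeline
consumes; they make no attempt at full assay realism (no batch effects,
doublets, ambient RNA, plate effects, or visit-schedule irregularities).
Passing tests therefore demonstrate correctness and calibration of the
*procedures* under the stated models, not robustness to every artifact of
real data.  All generators are bit-reproducible given (config, seed); a
single seed sequence is spawned into per-individual substreams.

* **Titers**: log-linear decay with patient random intercepts; sampling
  days uniform integers in the configured range (the simplest faithful
  stand-in for an irregular visit schedule).  Defaults are the reference
  conditions used throughout the tests: groups MGUS/SMM with slopes −0.0043 and
  −0.0085 log-titer/day, intercept 8, σ_u = 0.5, σ_e = 0.15, 3 samples per
  patient in days 14–120.  No external estimates of the variance components are available, so
  σ_u and σ_e are plausible defaults and remain configurable.
* **Repertoires**: background CDR3β are uniform random amino-acid strings
  with lengths uniform in 10–18, rejected whenever within Hamming
  distance ≤ 1 of any reference sequence, so planted fractions are exact
  ground truth.  Planted clones are copies of reference sequences or
  single-substitution variants (probability `mutation_rate = 0.5`), kept
  unique and strictly single-label.  Synthetic reference lists are
  star-shaped motif families whose centroids are ≥ 5 substitutions apart,
  so labels can never bridge at clustering radius 1.  Default cohort:
  12 individuals/group, 300 clonotypes/sample, CEF fraction 0.05 at both
  timepoints, spike 0.02 pre (expanding to 0.10 post only where
  configured).
* **Expression**: negative-binomial counts (mean/dispersion
  parameterization, dispersion 0.5) with per-gene means drawn log-normal
  (μ = 0.5, σ = 1 on the count-mean log scale) to create the expression
  strata that control-gene binning needs; module-gene means are boosted
  ×8 so planted log-scale shifts are representable in counts.  The
  additive module shift is planted through the log1p-normalization using
  stochastic rounding in log space (choosing between the two bracketing
  integer counts with the interpolation weight), which makes the planted
  mean shift unbiased; residual error is quantization variance plus a
  second-order total-count feedback.  Default cohort: 18 patients/group,
  40 cells each, 1,000 genes.
* **NPX**: per-individual protein offsets shared by both timepoints (so
  paired tests see only the planted shift), residual noise SD 0.3;
  planted post-vaccination shifts per (protein, group); for the burden
  group, APRIL is a decreasing linear function of an M-spike covariate
  uniform in 0.5–3.0 g/dL plus noise.  Default sizes mirror a small
  clinical proteomics cohort (13/14/18 per group) and the panel is the
  52-protein inflammation panel.

## Numerical and design choices

* LMM optimizer bounds log λ to [−15, 12]; the boundary fit λ = 0 is
  always evaluated and wins ties, flagged `singular_fit`.
* MCL non-convergence (rare; budget 100 iterations) falls back to the
  connected component with a warning rather than returning a partial
  iterate.
* Mixed co-clusters in specificity estimation confer no call
  (conservative, mirroring the panel's discard rule).
* The paired "Wilcoxon rank-sum" wording that sometimes appears for
  pre/post comparisons is implemented as the signed-rank test — the only
  paired Wilcoxon test — and the module documents this rather than
  guessing silently.
* Problem sizes in the test suite (e.g. 500 LRT replicates at the
  clinical cohort size, 100-seed detection-power runs with 300-clonotype
  repertoires, 50-seed estimator-recovery runs at 2,000 clonotypes) were
  chosen so each statistical property is measured with useful precision
  while the whole suite stays desk-scale.

## Known limitations

* Random intercepts only: no random slopes, splines, or assay-saturation
  censoring in the waning model.
* Clustering is exact-match-radius (Hamming ≤ 1, equal length) only — no
  V/J-gene-aware metrics, no epitope-level resolution.
* External-validation procedures accept local files in the generic
  formats; there is no GEO download client, and the packaged tests
  exercise them on synthetic stand-ins built at the external datasets'
  designs (4 donors × 5 timepoints; 9 vs 12 samples), not on the deposits
  themselves.
* The ELISPOT zero-control floor and the degenerate-difference limits in
  the validation t-tests are pragmatic conventions for cases the
  underlying tests leave undefined; both are flagged in output.
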