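# precvax

Vaccination immune-response analytics for myeloma precursor cohorts.

Monoclonal gammopathy of undetermined significance (MGUS) and smoldering
multiple myeloma (SMM) are clinically silent precursors of multiple
myeloma.  Whether patients in these states can mount and maintain normal
immune responses is a central question for infection management and cancer
immunotherapy.  `precvax` is a tested, reusable pipeline for analyzing
immune responses to SARS-CoV-2 vaccination — used as a standardized
immunological challenge — across the HD → MGUS → SMM → MM continuum:

1. **Antibody-waning kinetics** — windowed cross-sectional titer
   comparisons (Wilcoxon rank-sum, BH correction, rank-biserial effect
   sizes) and a longitudinal linear mixed model of log-titer decline,

   `log(titer)_ij = α_g(i) + β_g(i)·days_ij + u_i + ε_ij`,
   `u_i ~ N(0, σ_u²)`, `ε ~ N(0, σ_e²)`,

   fitted by maximum likelihood with disease-group-specific slopes β_g and
   compared against a common-slope model by likelihood-ratio test.
2. **Antigen-specific T-cell tracking** — CDR3β clonotypes are harmonized
   by exact amino-acid identity, clustered on the length-aware Hamming≤1
   graph with Markov clustering (expansion 2, inflation 2), co-clustered
   with a purity-filtered spike/CEF reference panel, and per-sample
   antigen-specific proportions estimated by bootstrapped subsampling
   (100 unique clonotypes × 10 iterations, averaged).
3. **Gene-module scoring** — per-cell score = mean log-normalized
   expression of a module (e.g. the 15-gene APRIL-responsive signature)
   minus the mean of expression-matched control genes; patient-level
   aggregation, group tests, per-gene BH panels, and the two external
   validation procedures (paired t-test stimulation time course;
   sample-level plasma-cell comparison).
4. **Proteomic response panels** — paired pre/post Olink-style NPX
   signed-rank panels with configurable BH families, cross-group rank-sum
   panels (52 proteins × 3 pairs = 156 tests per timepoint), and the
   Spearman correlation of APRIL with tumor burden (M-spike).

Patient-level data of this kind are access-controlled, so every stage is
exercised on synthetic cohorts from `precvax.synth`, whose generators
plant the effects of interest (group-specific waning slopes, an HD-only
post-vaccination spike-specific expansion, an additive module shift in one
group × timepoint stratum, group-graded NPX shifts and an APRIL–burden
link) as exactly recoverable ground truth.

## Worked example

The numbered scripts under `analysis/` run the full workflow on synthetic
cohorts (each is a thin driver over the library; all outputs land in
`results/`):

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_serology_waning.py
python analysis/03_tcr_specificity.py
python analysis/04_module_scoring.py
python analysis/05_proteomics.py
```

With seed 1 the serology stage prints

```
waning slopes (log-titer/day):
  MGUS: -0.00463
  SMM: -0.00846
LRT slope heterogeneity: stat=119.88, df=1, p=6.72e-28
```

i.e. the mixed model recovers the planted group slopes (−0.0043 and
−0.0085 natural-log-titer/day; SMM titers decay roughly twice as fast as
MGUS) and the LRT detects the slope heterogeneity — here with a huge
statistic because the simulated cohort (200 patients/group) is far larger
than a clinical cohort.  The TCR stage prints

```
spike pre/post HD: p=0.0025, paired r=+1.00
spike pre/post MGUS: p=0.1358, paired r=+0.50
spike pre/post SMM: p=0.3666, paired r=-0.31
cef pre/post HD: p=0.7595, paired r=-0.13
```

the planted pattern: a significant post-vaccination expansion of
spike-specific clonotypes only in healthy donors, with CEF (CMV/EBV/
influenza memory) proportions stable everywhere.  The scoring stage
detects the planted APRIL-module deficit in SMM B cells
(`p=3.2e-07, r=+1.00`, 14/15 genes at q<0.05) and the proteomics stage
reports the IL-1β/IL-18 response gradient and the inverse APRIL–M-spike
correlation (`rho=-0.86, p=5.4e-06, n=18`).

`analysis/06_report.py` runs everything through the orchestration layer
(`precvax.pipeline.run_pipeline`) from one config and renders a summary
report with a reproducibility manifest.

## Layout

```
src/precvax/      library: synth, io, stats, serology, tcr, scoring,
                  proteomics, pipeline
analysis/         numbered narrative drivers (simulate → analyze → report)
scripts/          acceptance.py
tests/            pytest suite (unit, property, and acceptance tests)
docs/methods.md   models, assumptions, parameter defaults, limitations
```
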