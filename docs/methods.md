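# Methods

This note documents the statistical models, default parameters, generator
scope, and numerical choices behind `festflow`. The package implements the
FEST (functional expansion of specific T cells) clonotype-calling assay
statistics and the companion single-cell analyses used around it: QC and
CD8 gating, clonotype linking, pseudobulk PCA with a permutation
association test, a cell-type composition-change test, gene-set signature
scores and marker calling, and a pseudotime dynamics test.

## Repertoire parsing and preprocessing

Clonotype tables are read from TSV in three dialects (`generic`, `airr`,
`adaptive`) and normalized to records of `(cdr3_aa, v_gene, reads,
productive, well_id)`. Preprocessing keeps only productive rearrangements
whose CDR3 amino-acid string obeys the canonical grammar — starts with C,
ends with F or W, length ≥ 7 — uppercases the sequence, and aggregates
duplicate `(cdr3_aa, well)` rows by summing reads. Samples with fewer
than 1,000 productive reads (strict) are excluded before calling; the
exclusion is reported, never silent.

## FEST caller

For a clonotype with `a` of `n1` reads in a stimulated culture and `b` of
`n2` reads in a reference, expansion is tested one-sided by the Fisher
exact test, i.e. the upper hypergeometric tail of `a` given the margins
(`scipy.stats.hypergeom.sf`). A clonotype is called antigen-specific for
a condition when all four criteria hold:

1. Benjamini–Hochberg FDR < 0.05 versus the no-peptide control;
2. FDR < 0.05 versus every other peptide condition, except conditions
   stimulated with peptides from the same mutation (`mutation_groups`);
3. odds ratio > 5 versus the control, with a Haldane–Anscombe +0.5
   correction on all four cells when any cell is zero;
4. present (≥ 1 read) in at least 10% of the condition's wells.

Only clonotypes with at least `read_floor` reads in the stimulated
condition are eligible (default 300, matching FTIC sequencing; 30 is the
documented setting for Adaptive-sequenced assays). FDR adjustment is
applied within each pairwise comparison family across that family's
eligible clonotypes. A triplicate mode covers assays with few peptides:
each replicate well is tested against the control, and a clone is
reactive when significant in ≥ 2 of 3 replicates and in no replicate of
any other condition.

## Single-cell QC, CD8 gating, clonotype linking

Cell filters (in order, reported per rule): detected genes < 250 or >
median + 3 × MAD (raw MAD, no normal-consistency scaling; with zero MAD
only the lower rule can remove); mitochondrial (`MT-`) count fraction
> 0.10 (strict); ribosomal (`RPL`/`RPS`) fraction < 0.10 (strict). Gene
filters: symbol prefixes `MT-`, `RP-`, and all TCR segment families
(`TRAV`…`TRGC`) plus user-supplied named lists; genes detected in < 5
cells. Cells are filtered before genes.

CD8 gating fits a Gaussian KDE (Silverman bandwidth) to per-cell CD8A
expression on a 512-point grid extended ±3 bandwidths, and cuts at the
first trough between the outermost *significant* modes (density ≥ 5% of
the maximum — tail wiggles are not bimodality). A unimodal density is a
hard error (`UnimodalDensityError`), not a silent all-pass. The default
gate input is `log2(CP10K + 1)`; any imputed or smoothed matrix may be
supplied instead.

Clonotype linking is by exact TRB CDR3 amino-acid match against
verdict-true FEST calls; a CDR3 matching clonotypes of two antigen
classes is flagged `ambiguous` rather than assigned.

## Pseudobulk PCA and the CC permutation test

Counts are summed per (cluster, sample) and scaled to a common library
size. Per cluster, highly variable genes are the positive residuals of a
LOESS fit (statsmodels `lowess`, `frac = 0.3`) of SD versus log mean;
when the fit is infeasible the fallback is the top-50% by SD with a
warning. Features `cluster::gene` from clusters observed in every sample
are standardized, concatenated, and embedded by PCA (≥ 3 samples
required; a missing (cluster, sample) combination is missing, never
imputed as zero).

Association between the embedding and a sample covariate uses the first
canonical correlation between the PC block and the dummy-coded covariate
(computed via QR then SVD, clipped to [0, 1]); the null permutes the
covariate across samples (optionally within strata) and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`. The embedding is sorted by
sample index first so p-values are exactly invariant to input row order.
Clusters are "MANA-enriched" when the labelled subset's share exceeds the
cluster's background share ≥ 2-fold.

## Composition-change test

For cell type `c` and timepoint `t`, `R_ct = m_ct / p_ct` is the labelled
subset's representation ratio relative to the background compartment, and
`S = Σ_c (R_c,T1 − R_c,T2)²`. The null holds a common pooled `R_c` per
type and redraws subset counts per timepoint from a multinomial with
probabilities ∝ `p_ct · R_c`, preserving each timepoint's subset total
exactly; p is add-one Monte-Carlo. A companion Fisher C×2 test is exact
by recursive column enumeration with log-gamma table probabilities for
totals ≤ 200, with a multivariate-hypergeometric Monte-Carlo fallback
beyond that; the two-sided p sums tables with probability ≤ observed
(+1e-9 relative tolerance against ties lost to rounding).

## Signature scores and markers

The module score bins all genes by rank of mean expression into 24
equal-count bins and, for each set gene, samples 100 control genes with
replacement from its bin; the score is mean(set) − mean(control draws,
with multiplicity). A global constant cancels exactly. The checkpoint
score is the module score of CTLA4, PDCD1, LAG3, HAVCR2, TIGIT, ENTPD1;
the exhaustion score takes a user gene list (the packaged list is a
synthetic stand-in, not a published signature).

Marker genes are one-vs-rest Wilcoxon rank-sum (`scipy.stats.
mannwhitneyu`, exact for both groups ≤ 8) with Bonferroni correction over
genes, retained when log2FC > 0.25 (`log2((mean(expm1 x)+1)/(mean(expm1
y)+1))` on log-normalized input), expressed in ≥ 25% of the group, and
corrected p < 0.05. Dose-response summaries report mean ± SEM per
(group, dose) (SEM flagged undefined for n < 2) with a Spearman trend
versus log dose.

## Pseudotime dynamics

Genes are retained when expression ≥ 0.01 in ≥ 1% of cells. Each gene is
fitted per sample with least-squares cubic B-splines (3 interior knots at
pseudotime quantiles, 7 basis functions) and compared to an
intercept-only model by the Gaussian likelihood ratio
`n·log(RSS0/RSS1)`, summed over samples. The null permutes pseudotime
within each sample; since the design is fixed, this equals permuting
expression, and null RSS1 comes from projections onto a precomputed
orthonormal basis of the design (RSS0 is permutation-invariant), giving
an exact and fast vectorized null. p-values are add-one; genes at BH
FDR < 0.05 are dynamic, and their mean (over samples) fitted curves,
standardized per gene, are clustered by k-means into patterns.
Pseudotime itself is an input; trajectory inference is out of scope.

## Synthetic-data generators

Generator defaults are the study conditions for all calibration claims
and were fixed before those claims were evaluated.

* **Repertoire**: clone frequencies from a symmetric Dirichlet(1) over
  200 clones; spiked clones multiply their frequency by the fold in the
  target condition before renormalizing; reads are per-well multinomial
  with the condition depth (default 10⁵ over 10 wells) conserved
  exactly; CDR3s are grammar-valid and unique.
* **Single cell**: Poisson-lognormal counts around per-cluster gene
  means (base log-mean −0.5, cluster SD 0.8) with covariate shifts on 20
  designated genes, multiplicative batch effects, and 30% dropout.
  Housekeeping `MT-*`/`RPL*`/`RPS*` genes are included so the QC fraction
  rules are exercised. CD8A is bimodal (±2 in log-mean) and exempt from
  dropout, emulating an imputed gate input. Clone sizes are power-law
  (exponent 1.5); labelled clones are enriched ~5-fold in designated
  clusters. The generator returns a truth record (clusters, DE genes,
  clone classes, CD8 truth).
* **Pseudotime**: rising / falling / transient / flat templates with
  Gaussian noise (SD 0.3), uniform pseudotime per sample.

Limits: no ambient RNA, doublets, UMI saturation, or cross-sample clone
sharing; expression and repertoire simulations are independent of each
other except through the linking labels.

## Pipeline and determinism

The pipeline runs the stages in dependency order from one YAML config
(unknown keys are hard errors; defaults are the documented thresholds).
Per-stage seeds derive from `numpy.random.SeedSequence.spawn` of the
config seed, reduced mod 2³¹. Output tables use a fixed `%.10g` float
format and every artifact gets a JSON sidecar with the config hash, seed
and package versions — no timestamps — so identical config + seed gives
byte-identical outputs.

## Problem sizes and calibration designs

The acceptance suite checks properties at desk scale; sizes are the
package's own choices, selected for statistical resolution within a
25-minute test budget:

* Fisher oracle: all 2×2 tables with both margins ≤ 60 (~3.6M tables)
  against an exhaustive enumeration via suffix-summed hypergeometric
  mass; agreement ≤ 1e-9 (observed ~1e-15).
* FEST calibration: 500 null simulations (depth 10⁵, 10 wells) for the
  false-call rate (≤ 0.05; observed 0) and 50 simulations × 3 spikes at
  20-fold for sensitivity (≥ 0.9; observed ~0.97–0.99).
* Composition: S = 0.72 on the hand-computable example; type-I error
  within 3 binomial SEs of 0.05 over 500 null datasets × 1,000 sims.
* CC test: 200 null repetitions at 500 permutations (KS uniformity at
  0.01) and 100 power repetitions of a 2-SD shift on 20/200 features
  with 6+6 samples (power ≥ 0.9; observed 1.0).
* CD8 gate: N(1, 0.3)/N(4, 0.5) equal mixture, n = 5,000; cutoff within
  ±0.3 of the analytic density minimum; misclassification ≤ Bayes
  error + 2 points.
* Pseudotime: flat-gene p-values uniform (KS) and ≥ 95% recovery of
  planted monotone genes (n = 300 cells, noise SD 0.3) at 250
  permutations (reduced from 1,000 for runtime; the add-one p floor
  1/251 still clears BH at these sizes).
* Markers: exact rank-sum enumeration for group sizes ≤ 8; planted
  log2FC = 1 recovered, log2FC ≈ 0.14 excluded at the documented
  thresholds.
* Module score: |mean| < 0.02 for a random set over exchangeable genes;
  shift invariance to 1e-6.
* Determinism: two pipeline runs byte-identical.

`scripts/acceptance.py --seed <int> --out <path>` recomputes these
quantities from scratch (FEST at 200 null / 30 spiked simulations to fit
a tighter budget) and writes them as JSON.

## Limitations

* The exhaustion gene list shipped in `festflow/data` is synthetic; real
  analyses must supply a published signature.
* The exact Fisher C×2 enumeration is exponential in the number of cell
  types; the ≤ 200 total cap keeps it tractable, beyond which the
  Monte-Carlo fallback applies.
* The LR permutation null assumes exchangeability of cells within a
  sample; covariates that structure cells within samples are not
  modelled.
* The CC permutation test with very few samples (e.g. 4) has a coarse
  attainable p-value floor; report the observed correlation alongside p.
* Batch standardization of pseudobulk profiles is a simple per-feature
  z-score; no empirical-Bayes batch correction is implemented.
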