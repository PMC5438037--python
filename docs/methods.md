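# Methods

`pwaskit` implements a pathway-wide association study (PWAS): instead of
testing single SNPs, it asks whether the SNPs mapped to a biological
pathway, taken together, can classify case-control status better than
chance, and whether the SNPs that drive those classifiers are enriched for
regulatory function.

## The association pipeline

For each pathway with candidate SNP pool *P* the discovery cohort is
processed in `n_iterations` (default 100) resampling iterations:

1. **Stratified 80/20 split.** Cases and controls are split separately
   (fraction rounded half up per class) into a selection set and a test
   set.
2. **Subsampled mRmR consensus selection.** Ten stratified 80% subsamples
   of the selection set each run greedy maximum-relevance
   minimum-redundancy selection for `k_features` SNPs.  Relevance is the
   plug-in mutual information (bits) between the additive genotype
   (0/1/2) and the label; redundancy is the mean MI with already-selected
   SNPs; the score is relevance − redundancy (`difference`, default) or
   relevance / redundancy (`quotient`).  Missing genotypes are
   pairwise-deleted; no pseudo-counts.  Ties break on genomic order
   (chrom, position, snp_id).  SNPs chosen in ≥ `consensus_min` (default
   5) of the ten runs form the iteration's SNP set.
3. **Two-feature rule.** A pathway whose consensus set holds fewer than
   two SNPs in *any* iteration is excluded from the association family
   (its selection trace is still completed so appearance rates remain
   defined).
4. **Under-sampled random forest.** The majority class of the selection
   set is randomly down-sampled to the minority count; a random forest
   (pinned defaults: 500 trees, √p candidate features per split,
   unlimited depth; missing genotypes mode-imputed from the training set)
   is fitted on the selected SNPs.
5. **Evaluation.** The classifier's case probabilities are scored on the
   20% test set, on an independent validation cohort when one exists, and
   on label-permuted copies of those same evaluation sets (one fresh
   permutation per iteration; the trained classifier is identical, only
   labels shuffle).  Metrics: sensitivity, specificity, accuracy at the
   0.5 probability threshold, mid-rank AUC, and the confusion-matrix odds
   ratio (tp·tn)/(fp·fn) with the Haldane–Anscombe +0.5 correction when
   any cell is zero.

Across iterations: point estimates and 95% CIs are the mean ± 1.96·SE of
the iteration metrics (percentile CIs available); the pathway p-value is a
two-sided Welch t-test between the real and permuted odds-ratio samples;
Benjamini–Hochberg adjustment runs over all non-excluded pathways.
Variance explained is the Nagelkerke pseudo-R²,
R²_N = [1 − (L₀/L₁)^(2/n)] / [1 − L₀^(2/n)], of a logistic model of case
status on the out-of-sample classifier probability (a dosage-matrix
predictor is available, and is what `combined_r2` uses for unions of
pathway SNP sets).  Perfect separation is reported as a flagged
upper-bound value of 1.  Estimates use the validation cohort when
supplied, else the 20% test split.

**Seeding.**  Every stochastic stage draws from
`SeedSequence(master_seed, spawn_key=(crc32(pathway_id), iteration,
stage))`, so runs are reproducible byte-for-byte and invariant to pathway
execution order (safe to parallelize per pathway).

## SNP→gene→pathway mapping

A SNP maps to a gene when it lies within an asymmetric intergenic window:
2 kb upstream of the 5′ end and 0.5 kb downstream of the 3′ end,
strand-reflected; coordinates are 0-based half-open internally (1-based
`.map` input converted at the boundary).  SNPs may map to several
overlapping genes and are retained in every pathway containing any of
them.  GMT symbols match case-insensitively after whitespace stripping; a
configurable exclusion list drops umbrella gene sets whose members are
already covered by their constituent pathways.

## Quality control

Fixed filter order: user exclusion list → sample missingness (default
max 2%) → SNP missingness (5%) → MAF floor (1%) → Hardy–Weinberg exact
test in controls only (p ≥ 1e-6, no mid-p).  The HWE test conditions on
allele counts and uses a log-space ratio recurrence, so it is stable for
arbitrarily large cohorts.  Ancestry and relatedness filtering are out of
scope; the exclusion-list hook accepts externally derived sample lists.

## Gene-level reporting and functional enrichment

A SNP's **appearance rate** is the fraction of resampling iterations whose
consensus set contained it.  Gene contributions are the sum of a gene's
SNP rates normalized by its number of LD tag SNPs (greedy pruning in
genomic order at r² ≥ 0.50, with r² the squared Pearson correlation of
additive codes — allele-flip invariant).

For enrichment, SNPs are binned by appearance rate into fixed quartiles
(0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1]; never-selected SNPs are
excluded.  Statistics: the proportion of SNPs with an eQTL p < 0.05 for a
gene the SNP maps to, and a weighted Regulome score using a declared
monotone, evenly spaced weight table over the 15 public RegulomeDB-style
categories (1a=7 … 7=0; exposed as data so the original weights can be
substituted).  The candidate statistic is compared against one value per
background SNP set — non-significant pathways' selected SNP sets by
default, or random SNP sets of equal size — with a two-sided one-sample
t-test of the background sample against the candidate value, reporting
direction (enriched/depleted).

## The synthetic-data generator

The generator emulates the restricted case-control GWAS inputs end to
end so the pipeline is testable without any download: genes on synthetic
chromosomes (5 kb genes, 20 kb gaps — wider than the mapping windows),
pathway gene sets dealt from a shuffled gene list with wrap-around (so
overlap appears exactly when total demanded membership exceeds the gene
count), per-gene LD blocks in which each SNP copies the previous SNP's
allele per haplotype with probability √(ld_block_r2) (all SNPs of a block
share the block MAF, making the adjacent-pair genotype r² equal
`ld_block_r2` in expectation), and uniform missingness.  Case status
follows a logistic model over the causal pathways' SNPs with per-allele
log-odds `effect_size_beta`; the intercept is calibrated by bisection so
the expected case fraction matches the requested cohort sizes, then
cases/controls are collected by batch rejection sampling (bounded at 100×
the target).  Functional tables give every SNP an eQTL p-value (10%
background chance of p < 0.05) and a Regulome category (20% background
chance of the strong 1a–2c group), with causal SNPs boosted by the
configured odds multiplier.

Defaults (1000/1000 samples, 300 genes × 3 SNPs, 50 pathways of 4 genes,
2 causal pathways × 2 causal SNPs, β = 0.4, MAF ∈ [0.05, 0.5], block
r² = 0.5, 1% missingness, 5× functional odds) emulate a desk-scale cohort
aiming at the modest pathway odds-ratio regime (< 1.35) such studies
report.  The generator is cleaner than real data — causal SNPs are typed
directly, with no LD dilution or stratification — so at a fixed per-allele
effect its classifiers outperform real-data counterparts: architectures
strong enough for highly reliable pathway ranking produce ORs around
1.5, while architectures confined to the sub-1.35 regime are detected
less reliably.  The calibration experiments report both sides of that
trade-off honestly.  What the generator does **not** model: realistic
haplotype structure (no recombination maps or coalescent), population
stratification, relatedness, X-chromosome effects, genotyping batch
artifacts.  Tests passing on this generator therefore validate the
pipeline's mechanics and statistical behavior, not robustness to those
real-data complications.

## Statistical behavior: what the calibration experiments show

Two properties of the published statistical design surface clearly on
synthetic nulls, and are reported here as method limitations rather than
masked:

* **The iteration-wise permutation t-test is anticonservative.**  All
  resampling iterations re-split one finite cohort, so every iteration's
  odds ratio shares that cohort's chance SNP-label associations (and the
  mRmR step actively enriches for them).  The Welch t-test treats the
  iterations as independent, so under a global null it rejects far above
  nominal (≈28% at α = 0.05 with n = 600, 20 iterations, 20%-test
  evaluation; a fixed independent validation cohort makes it worse, since
  a larger evaluation set shrinks iteration noise but not the shared
  cohort-noise offset).  Planted-effect recovery is unaffected — causal
  pathways dominate the ranking — but raw and BH-adjusted p-values from
  this design should be read as ranking scores, not calibrated error
  rates.
* **The one-sample enrichment t-test ignores candidate noise.**  The
  candidate statistic is computed from a handful of high-appearance SNPs
  and is itself a noisy draw; testing the background sample against it as
  a fixed hypothesized mean inflates the null flag rate to ≈40–65% with
  8–16 backgrounds (t ~ N(0, m+1) when candidate and background values
  share a variance).  Planted five-fold enrichment is still recovered
  essentially always; isolated flags should be treated as descriptive.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo experiments run at desk scale, chosen once: null calibration
uses 10 cohorts (4 in the script) of n = 600 with 50 three-gene pathways,
20 iterations, 15 trees; parameter recovery uses 10 replicates (3 in the
script) of n = 3000 with 2 causal among 12 four-gene pathways, β = 0.4,
50 iterations, 25 trees; enrichment recovery uses n = 600, 2 causal among
10 pathways, β = 0.7, 20 iterations.  Reduced tree counts relative to the
pinned 500-tree default trade classifier smoothness for throughput; they
leave calibration properties unchanged and recovery power ample at the
planted effect sizes.

## Known limitations

Beyond the calibration points above: the consensus rule for combining the
ten subsample mRmR runs into one iteration SNP set is this package's
interpretation (majority, configurable); the mRmR variant (difference) and
per-run feature count are likewise configurable because the source design
leaves them open; PLINK binary formats are not parsed (text .ped/.map and
TSV matrices are); and the Regulome weight table is a declared stand-in
exposed as configuration data.
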