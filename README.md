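# pwaskit

Pathway-wide association studies (PWAS) for case-control genotype data.

Single-SNP genome-wide association struggles with polygenic disorders
whose risk alleles replicate poorly across populations.  A pathway-wide
association study shifts the unit of analysis from the SNP to the
biological pathway: for every curated gene set, the SNPs mapping to its
genes are treated as a candidate feature pool, a classifier is trained on
selected SNPs, and the pathway is scored by how much better than a
permuted-label null its classifier separates cases from controls.
`pwaskit` is a tested, reusable implementation of that design for
statistical geneticists and methods researchers, together with a
synthetic-data generator that emulates the (access-restricted) inputs of
such studies so every stage can be exercised end to end on a laptop.

## The method

For each pathway, over 100 stratified 80/20 resampling iterations of the
discovery cohort:

* **mRmR SNP selection** on ten 80% subsamples of the selection set —
  greedy maximum-relevance minimum-redundancy with plug-in mutual
  information *I(g; y)* in bits; SNPs chosen in ≥5/10 runs form the
  iteration's SNP set (pathways dropping below two SNPs in any iteration
  are excluded);
* **under-sampled random forest** — the majority class is down-sampled to
  the minority count, a forest is fitted on the selected SNPs and applied
  to the held-out 20% (and to an independent validation cohort when
  available), plus to label-permuted copies of the same evaluation sets;
* **association statistics** — sensitivity, specificity, accuracy, mid-rank
  AUC and the confusion-matrix odds ratio OR = (TP·TN)/(FP·FN) per
  iteration; the pathway p-value is a Welch t-test of real vs permuted
  ORs, Benjamini–Hochberg-adjusted across pathways; variance explained is
  the Nagelkerke pseudo-R²
  R²_N = [1 − (L₀/L₁)^{2/n}] / [1 − L₀^{2/n}];
* **functional enrichment** — each SNP's *appearance rate* (fraction of
  iterations selecting it) bins SNPs into quartiles; eQTL proportions and
  weighted RegulomeDB-style scores of high-appearance SNPs are contrasted
  against non-significant-pathway SNP sets with a one-sample t-test.

Gene-level contributions normalize summed SNP appearance rates by the
gene's number of LD tag SNPs (greedy pruning at r² ≥ 0.50).

See `docs/methods.md` for assumptions, parameter defaults, the
synthetic-data model, and two documented calibration caveats of the
published statistical design.

## Worked example

`examples/simulate_and_associate.py` simulates 400 cases / 400 controls,
48 genes in 12 pathways with two causal pathways planted (β = 0.6 per
allele), then runs QC → mapping → association (25 iterations):

```
Planted causal pathways: ['PW005', 'PW011']

pathway_id    auc     or  or_lo  or_hi     p_raw      p_bh  nagelkerke_r2
     PW011 0.6172  2.245  1.971  2.519  8.09e-07 9.708e-06        0.05148
     PW005 0.5851  1.917   1.58  2.255 0.0007252  0.004351        0.03535
     PW008 0.4904 0.9285 0.7998  1.057   0.02891    0.1156       0.006668
     PW001 0.4992  1.085 0.8707  1.298    0.3975    0.6814       0.008073
     ...
```

Both planted pathways head the table: their classifiers beat the
permuted-label null (BH-adjusted p < 0.005) with odds ratios near 2 and
explain 3.5–5% of liability variance, while the ten null pathways sit at
chance (AUC ≈ 0.5, OR ≈ 1).  The other example scripts demonstrate the
selection machinery (`feature_selection_demo.py`), file formats and QC
(`qc_and_formats_demo.py`), and appearance-rate functional enrichment
(`functional_enrichment_demo.py`).

A thin CLI mirrors the pipeline stages for shell use:

```bash
pwaskit simulate --config sim.yaml --out data/
pwaskit qc --genotypes data/genotypes --format plink_text --out qc/
pwaskit map --snps qc/qc_snps.tsv --annotation data/genes.bed \
            --gene-sets data/pathways.gmt --out pools.tsv
pwaskit run --config run.yaml
pwaskit functional --results run/results.tsv --traces run/traces.tsv \
                   --eqtl data/eqtl.tsv --regulome data/regulome.tsv --out grid.tsv
pwaskit report --results run/results.tsv --traces run/traces.tsv \
               --genotypes qc/qc_genotypes.tsv --mapping run/mapping.tsv --out report/
```

Every stage writes plain-text artifacts and a `manifest.json` (config
hash, seed, versions); a fixed master seed reproduces all outputs
byte-for-byte.

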