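"""End-to-end pathway-wide association on a simulated case-control study.

Builds a small synthetic cohort with two causal pathways, runs QC, SNP->
gene->pathway mapping, and the resampled mRmR + random-forest association
pipeline, then prints the per-pathway summary table.
"""

from pwaskit import (
    ForestConfig,
    MrmrConfig,
    SimulationConfig,
    run_synthetic_pwas,
)
from pwaskit.stats import results_frame

cfg = SimulationConfig(
    n_cases=400, n_controls=400, n_genes=48, snps_per_gene=3, n_pathways=12,
    genes_per_pathway=4, n_causal_pathways=2, causal_snps_per_pathway=4,
    effect_size_beta=0.6, missing_rate=0.01, seed=7,
)
run = run_synthetic_pwas(
    cfg,
    mrmr=MrmrConfig(k_features=5),
    forest=ForestConfig(n_trees=50),
    n_iterations=25,
    master_seed=1,
)

print("QC report:")
print(run.qc_report.to_frame().to_string(index=False))
print(f"\nPlanted causal pathways: {run.causal_pathways}\n")

df = results_frame(run.results).sort_values("p_bh")
cols = ["pathway_id", "auc", "or", "or_lo", "or_hi", "p_raw", "p_bh", "nagelkerke_r2"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))

print(
    "\nEach row is one pathway classifier evaluated over 25 resampling "
    "iterations: 'or' is the mean confusion-matrix odds ratio with its 95% CI, "
    "'p_raw' the Welch t-test against the permuted-label odds ratios, 'p_bh' "
    "its Benjamini-Hochberg adjustment, and 'nagelkerke_r2' the liability "
    "variance explained by the classifier score. The planted pathways should "
    "sit at the top with odds ratios above 1."
)
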