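"""Appearance-rate quartiles and functional enrichment of selected SNPs.

Runs the pipeline on a study whose causal SNPs are enriched for eQTL and
regulatory annotations (five-fold odds), then contrasts high-appearance
SNPs of the significant pathways against non-significant-pathway SNP sets.
"""

from pwaskit import (
    ForestConfig,
    MrmrConfig,
    SimulationConfig,
    eqtl_proportion,
    functional_report,
    quartile_bins,
    run_synthetic_pwas,
)
from pwaskit.stats import results_frame

run = run_synthetic_pwas(
    SimulationConfig(
        n_cases=300, n_controls=300, n_genes=40, snps_per_gene=3, n_pathways=10,
        genes_per_pathway=4, n_causal_pathways=2, causal_snps_per_pathway=4,
        effect_size_beta=0.7, missing_rate=0.0, functional_enrichment_odds=5.0,
        seed=12,
    ),
    mrmr=MrmrConfig(k_features=5),
    forest=ForestConfig(n_trees=50),
    n_iterations=20,
    master_seed=4,
)
df = results_frame(run.results).set_index("pathway_id")
tested = df.loc[~df["excluded"]]
sig = tested.index[tested["p_bh"] < 0.05].tolist()
print(f"significant pathways: {sig} (planted causal: {run.causal_pathways})")

rates = {pid: run.traces[pid].rates() for pid in df.index}

# quartile contrast pooled over the significant pathways
pooled: dict[str, float] = {}
for pid in sig:
    for snp, r in rates[pid].items():
        pooled[snp] = max(pooled.get(snp, 0.0), r)
bins = quartile_bins(pooled)
for q in ("Q1", "Q2", "Q3", "Q4"):
    snps = [s for s, b in bins.items() if b == q]
    if snps:
        prop = eqtl_proportion(snps, run.study.eqtl)
        print(f"  {q}: {len(snps):3d} SNPs, eQTL proportion {prop:.2f}")

grid = functional_report(
    {pid: rates[pid] for pid in sig},
    [list(rates[pid]) for pid in tested.index if tested.loc[pid, "p_bh"] >= 0.05],
    run.study.eqtl,
    run.study.regulome,
)
print("\nenrichment grid (candidate vs non-significant-pathway background):")
print(grid.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

print(
    "\nSNPs that represent a causal pathway in >75% of iterations (Q4) carry "
    "the planted functional labels, so their eQTL proportion rises from Q1 to "
    "Q4 and the grid flags the causal pathways as enriched. The one-sample "
    "t-test ignores the candidate's own sampling noise, so treat borderline "
    "flags with caution (see docs/methods.md)."
)
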