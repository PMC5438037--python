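"""Subsampled mRmR consensus selection and appearance rates for one pathway.

Shows the selection machinery in isolation: mutual information of each SNP
with case status, one greedy mRmR run, the 10-subsample consensus, and
appearance rates accumulated over repeated stratified resampling.
"""

import numpy as np

from pwaskit import (
    MrmrConfig,
    SimulationConfig,
    consensus_select,
    mrmr_select,
    mutual_information,
    simulate_study,
    stratified_split,
)
from pwaskit.selection import SelectionTrace

study = simulate_study(
    SimulationConfig(
        n_cases=300, n_controls=300, n_genes=4, snps_per_gene=3, n_pathways=1,
        genes_per_pathway=4, n_causal_pathways=1, causal_snps_per_pathway=3,
        effect_size_beta=0.6, missing_rate=0.0, seed=3,
    )
)
ds = study.dataset
X, y = ds.genotypes, ds.phenotypes
ids = ds.snp_ids.tolist()
causal = set(study.causal_snp_ids)

print("per-SNP relevance I(genotype; case status), bits:")
for j, snp in enumerate(ids):
    tag = " (causal)" if snp in causal else ""
    print(f"  {snp}: {mutual_information(X[:, j], y):.4f}{tag}")

cfg = MrmrConfig(k_features=4, seed=11)
picks = mrmr_select(X, y, cfg)
print("\none greedy mRmR run (k=4), in selection order:", [ids[j] for j in picks])

consensus, runs = consensus_select(X, y, cfg)
print(f"consensus over {cfg.n_subsamples} stratified 80% subsamples "
      f"(kept if chosen in >= {cfg.consensus_min}):", [ids[j] for j in consensus])

iterations = []
for it in range(20):
    sel_idx, _ = stratified_split(y, 0.8, rng=it)
    cons, _ = consensus_select(X[sel_idx], y[sel_idx], cfg,
                               np.random.default_rng(1000 + it))
    iterations.append(tuple(ids[j] for j in cons))
trace = SelectionTrace("demo_pathway", iterations)
print("\nappearance rates over 20 resampling iterations:")
for snp, rate in sorted(trace.rates().items(), key=lambda kv: -kv[1]):
    tag = " (causal)" if snp in causal else ""
    print(f"  {snp}: {rate:.2f}{tag}")

print(
    "\nCausal SNPs carry the most label information, survive the redundancy "
    "penalty, and are selected in (nearly) every iteration - their appearance "
    "rate approaches 1, the quantity later used for functional enrichment."
)
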