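"""Gene-level contribution reporting.

Turns per-SNP appearance rates into per-gene contributions: a gene's rate
is the sum of its SNPs' appearance rates normalized by its number of LD tag
SNPs (greedy pruning at r-squared 0.50), so genes dense in redundant SNPs
are not over-credited.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .dataset import GenotypeDataset
from .selection import gene_appearance_rate, greedy_tag_snps

__all__ = ["gene_contribution_table"]


def gene_contribution_table(
    rates_by_pathway: Mapping[str, Mapping[str, float]],
    mapping: pd.DataFrame,
    ds: GenotypeDataset,
    r2_threshold: float = 0.5,
    min_total_rate: float = 0.0,
) -> pd.DataFrame:
    """Normalized gene appearance rates for each pathway.

    ``mapping`` is the SNP->gene table from
    :func:`~pwaskit.pathways.assign_snps_to_genes`; tag counts are computed
    from ``ds`` genotypes per gene.  Rows with a normalized rate below
    ``min_total_rate`` are dropped.  Returns columns
    ``pathway_id, gene_id, n_snps, n_tag_snps, gene_rate``.
    """
    gene_to_snps = mapping.groupby("gene_id")["snp_id"].apply(list).to_dict()
    tag_cache: dict[str, int] = {}

    def tags(gene: str) -> int:
        if gene not in tag_cache:
            cols = ds.snp_indices(gene_to_snps[gene])
            tag_cache[gene], _ = greedy_tag_snps(ds.genotypes[:, cols], r2_threshold)
        return tag_cache[gene]

    rows = []
    for pid, rates in rates_by_pathway.items():
        selected = set(rates)
        genes = sorted(
            {g for g, snps in gene_to_snps.items() if selected.intersection(snps)}
        )
        sub = {g: gene_to_snps[g] for g in genes}
        tag_counts = {g: max(tags(g), 1) for g in genes}
        gene_rates = gene_appearance_rate(rates, sub, tag_counts)
        for g in genes:
            if gene_rates[g] >= min_total_rate:
                rows.append((pid, g, len(sub[g]), tag_counts[g], gene_rates[g]))
    return pd.DataFrame(
        rows, columns=["pathway_id", "gene_id", "n_snps", "n_tag_snps", "gene_rate"]
    )
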