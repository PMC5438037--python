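"""SNP -> gene -> pathway mapping.

SNPs are assigned to genes with an asymmetric intergenic window: 2 kb
upstream of the transcription start (5') and 0.5 kb downstream of the end
(3'), reflected for minus-strand genes.  Coordinates are 0-based half-open
throughout; 1-based inputs are converted at the I/O boundary.  A SNP may map
to several overlapping genes and is kept in every pathway containing any of
them — pathway pools are feature universes, not counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = ["assign_snps_to_genes", "build_pathway_pools", "PathwaySnpPool", "write_pool_table"]

logger = logging.getLogger(__name__)


def assign_snps_to_genes(
    snp_meta: pd.DataFrame,
    genes: pd.DataFrame,
    window5: int = 2000,
    window3: int = 500,
) -> pd.DataFrame:
    """Map SNPs to genes using the asymmetric 5'/3' intergenic window.

    A SNP at position ``x`` maps to a plus-strand gene ``[start, end)`` iff
    ``start - window5 <= x < end + window3``; for minus-strand genes the
    windows swap ends.  Returns one row per (snp, gene) pair with columns
    ``snp_id, gene_id, chrom, position``, sorted by (chrom, position,
    snp_id, gene_id).
    """
    if window5 < 0 or window3 < 0:
        raise ConfigurationError("windows: must be >= 0")
    out = []
    snps_by_chrom = dict(tuple(snp_meta.groupby("chrom", sort=False)))
    for gene in genes.itertuples(index=False):
        chrom_snps = snps_by_chrom.get(gene.chrom)
        if chrom_snps is None:
            continue
        pos = chrom_snps["position"].to_numpy()
        if gene.strand == "+":
            lo, hi = gene.start - window5, gene.end + window3
        else:
            lo, hi = gene.start - window3, gene.end + window5
        hit = (pos >= lo) & (pos < hi)
        if hit.any():
            sub = chrom_snps.loc[hit, ["snp_id", "chrom", "position"]].copy()
            sub["gene_id"] = gene.gene_id
            out.append(sub)
    if not out:
        mapping = pd.DataFrame(columns=["snp_id", "gene_id", "chrom", "position"])
    else:
        mapping = pd.concat(out, ignore_index=True)[["snp_id", "gene_id", "chrom", "position"]]
    return mapping.sort_values(
        ["chrom", "position", "snp_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class PathwaySnpPool:
    """A pathway's candidate SNP universe before feature selection."""

    pathway_id: str
    gene_ids: list[str]
    snp_ids: list[str]
    warning: str | None = field(default=None)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def build_pathway_pools(
    mapping: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    exclude: set[str] | None = None,
) -> list[PathwaySnpPool]:
    """Build one :class:`PathwaySnpPool` per non-excluded pathway.

    GMT gene symbols are matched case-insensitively after whitespace
    stripping; unresolvable symbols are logged, not fatal.  SNP order within
    a pool is deterministic: (chrom, position, snp_id), deduplicated.
    """
    if not gene_sets:
        raise DataError("empty gene-set collection")
    exclude = exclude or set()
    mapping = mapping.assign(_gene_key=mapping["gene_id"].str.strip().str.lower())
    by_gene = dict(tuple(mapping.groupby("_gene_key", sort=False)))
    pools = []
    for pid, symbols in gene_sets.items():
        if pid in exclude:
            continue
        warning = None
        frames = []
        for sym in symbols:
            sub = by_gene.get(sym.strip().lower())
            if sub is None:
                logger.warning("pathway %s: gene %r resolved no SNPs", pid, sym)
                continue
            frames.append(sub)
        if frames:
            merged = pd.concat(frames).sort_values(
                ["chrom", "position", "snp_id"], kind="mergesort"
            )
            snp_ids = list(dict.fromkeys(merged["snp_id"]))
        else:
            snp_ids = []
        if len(snp_ids) < 1:
            warning = "empty SNP pool"
        pools.append(PathwaySnpPool(pid, list(symbols), snp_ids, warning))
    return pools


def write_pool_table(pools: list[PathwaySnpPool], path: str | Path) -> None:
    rows = [
        (p.pathway_id, len(p.gene_ids), p.n_snps, ",".join(p.snp_ids)) for p in pools
    ]
    pd.DataFrame(rows, columns=["pathway_id", "n_genes", "n_snps", "snp_ids"]).to_csv(
        path, sep="\t", index=False
    )
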