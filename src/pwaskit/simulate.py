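"""Synthetic case-control GWAS generator with planted pathway effects.

The generator emulates the restricted inputs of a pathway-wide association
study so that every downstream stage is testable without any data download:

* genes laid out on synthetic chromosomes, grouped into (possibly
  overlapping) pathway gene sets;
* biallelic autosomal SNPs with additive 0/1/2 coding, per-gene LD blocks
  under a block-copy model, and uniform missingness;
* case status drawn from a logistic model over the SNPs of a few "causal"
  pathways, with the intercept calibrated by bisection so the realized case
  fraction matches the requested cohort sizes;
* matching eQTL and regulatory-annotation tables in which the planted causal
  SNPs are enriched for functional labels by a configurable odds multiplier.

Within a gene, each SNP copies the previous SNP's allele (per haplotype)
with probability ``sqrt(ld_block_r2)``, else draws a fresh allele at the
block MAF; all SNPs of a block share the block's MAF, which makes the
adjacent-pair genotype r-squared equal ``ld_block_r2`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .config import SimulationConfig
from .dataset import MISSING, GenotypeDataset
from .errors import DataError, SimulationError
from .functional import REGULOME_CATEGORIES

__all__ = [
    "simulate_annotation",
    "simulate_genotypes",
    "simulate_functional_tables",
    "simulate_study",
    "SimulatedStudy",
]

_GENE_SPAN = 5_000  # bp per gene
_GENE_GAP = 20_000  # intergenic gap, comfortably wider than mapping windows
_GENES_PER_CHROM = 25

# background functional rates the enrichment odds act on
_EQTL_BACKGROUND_RATE = 0.10  # P(eQTL p-value < 0.05) for a non-causal SNP
_REGULOME_FUNCTIONAL_RATE = 0.20  # P(category in the "functional" 1a..2c group)
_FUNCTIONAL_GROUP = [c for c in REGULOME_CATEGORIES if c[0] in "12"]
_NONFUNCTIONAL_GROUP = [c for c in REGULOME_CATEGORIES if c[0] not in "12"]


def _odds_boost(base_rate: float, odds: float) -> float:
    """Apply an odds multiplier to a probability."""
    return base_rate * odds / (1.0 - base_rate + base_rate * odds)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate a gene annotation table and pathway gene sets.

    Returns ``(genes, gene_sets)``: a BED-like DataFrame with columns
    ``chrom, start, end, strand, gene_id`` and a ``{pathway_id: [gene_id]}``
    mapping.  Pathway membership deals shuffled genes out sequentially and
    wraps around, so pathways share genes exactly when the total demanded
    membership exceeds ``n_genes``.
    """
    rng = derive_rng(cfg.seed, 0)
    rows = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        slot = i % _GENES_PER_CHROM
        start = _GENE_GAP + slot * (_GENE_SPAN + _GENE_GAP)
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, start + _GENE_SPAN, strand, f"G{i + 1:04d}"))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    dealt = rng.permutation(genes["gene_id"].to_numpy())
    sizes = rng.integers(
        cfg.genes_per_pathway[0], cfg.genes_per_pathway[1] + 1, size=cfg.n_pathways
    )
    gene_sets: dict[str, list[str]] = {}
    cursor = 0
    for p, size in enumerate(sizes):
        members = [dealt[(cursor + k) % len(dealt)] for k in range(size)]
        cursor += size
        gene_sets[f"PW{p + 1:03d}"] = members
    return genes, gene_sets


# ---------------------------------------------------------------------------
# genotypes + phenotype
# ---------------------------------------------------------------------------

def _draw_block(rng: np.random.Generator, n: int, m: int, maf: float, copy_p: float) -> np.ndarray:
    """Additive genotypes for one LD block: n samples x m SNPs."""
    g = np.zeros((n, m), dtype=np.int8)
    for hap in range(2):
        a = np.empty((n, m), dtype=np.int8)
        a[:, 0] = rng.random(n) < maf
        for j in range(1, m):
            fresh = rng.random(n) < maf
            copy = rng.random(n) < copy_p
            a[:, j] = np.where(copy, a[:, j - 1], fresh)
        g += a
    return g


def _calibrate_intercept(scores: np.ndarray, target: float, tol: float = 1e-3) -> float:
    """Bisect the logistic intercept so mean case probability hits ``target``."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        frac = float(np.mean(1.0 / (1.0 + np.exp(-(mid + scores)))))
        if abs(frac - target) < tol:
            return mid
        if frac < target:
            lo = mid
        else:
            hi = mid
    raise SimulationError("intercept calibration failed: case fraction unattainable")


def simulate_genotypes(
    cfg: SimulationConfig,
    annotation: tuple[pd.DataFrame, dict[str, list[str]]],
) -> GenotypeDataset:
    """Draw a case-control genotype dataset with planted pathway effects.

    Sampling continues (in batches) until exactly ``n_cases`` and
    ``n_controls`` are collected, bounded at 100x the target sample count.
    Planted truth travels on ``snp_meta`` columns ``gene_id``, ``maf``,
    ``is_causal``, ``beta`` and ``causal_pathway``.
    """
    genes, gene_sets = annotation
    rng = derive_rng(cfg.seed, 1)

    # --- SNP layout: per-gene blocks sharing the block MAF ---------------
    snp_rows = []
    block_sizes = []
    block_mafs = []
    snp_counter = 0
    for row in genes.itertuples(index=False):
        m = int(rng.integers(cfg.snps_per_gene[0], cfg.snps_per_gene[1] + 1))
        maf = float(rng.uniform(*cfg.maf_range))
        block_sizes.append(m)
        block_mafs.append(maf)
        positions = np.linspace(row.start, row.end - 1, m).astype(int)
        for pos in positions:
            snp_counter += 1
            snp_rows.append((f"rs{snp_counter:06d}", row.chrom, int(pos), "A", "B", row.gene_id, maf))
    snp_meta = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "chrom", "position", "allele_a", "allele_b", "gene_id", "maf"],
    )
    n_snps = len(snp_meta)

    # --- plant causal SNPs -----------------------------------------------
    causal_paths = sorted(
        rng.choice(sorted(gene_sets), size=cfg.n_causal_pathways, replace=False).tolist()
    )
    gene_snp_idx = {g: idx.to_numpy() for g, idx in snp_meta.groupby("gene_id").groups.items()}
    is_causal = np.zeros(n_snps, dtype=bool)
    causal_pathway = np.array([""] * n_snps, dtype=object)
    for pid in causal_paths:
        member_genes = gene_sets[pid]
        chosen: list[int] = []
        offset = 0
        while len(chosen) < cfg.causal_snps_per_pathway:  # round-robin over genes
            progressed = False
            for g in member_genes:
                idx = gene_snp_idx[g]
                if offset < len(idx) and not is_causal[idx[offset]]:
                    chosen.append(idx[offset])
                    progressed = True
                    if len(chosen) == cfg.causal_snps_per_pathway:
                        break
            offset += 1
            if not progressed and offset > max(len(gene_snp_idx[g]) for g in member_genes):
                raise SimulationError(
                    f"pathway {pid}: not enough distinct SNPs for causal_snps_per_pathway"
                )
        is_causal[chosen] = True
        causal_pathway[chosen] = pid
    snp_meta["is_causal"] = is_causal
    snp_meta["beta"] = np.where(is_causal, cfg.effect_size_beta, 0.0)
    snp_meta["causal_pathway"] = causal_pathway

    causal_idx = np.flatnonzero(is_causal)
    betas = snp_meta["beta"].to_numpy()[causal_idx]
    # center causal genotypes at 2*maf so the raw score is mean-zero
    causal_offset = 2.0 * snp_meta["maf"].to_numpy()[causal_idx]

    # --- batch rejection sampling ----------------------------------------
    n_target = cfg.n_samples
    batch = max(2 * n_target, 500)
    max_draws = 100 * n_target
    block_starts = np.cumsum([0] + block_sizes)

    def draw_batch(b: int) -> tuple[np.ndarray, np.ndarray]:
        G = np.empty((b, n_snps), dtype=np.int8)
        for k, (m, maf) in enumerate(zip(block_sizes, block_mafs)):
            G[:, block_starts[k]:block_starts[k + 1]] = _draw_block(
                rng, b, m, maf, np.sqrt(cfg.ld_block_r2)
            )
        score = (G[:, causal_idx].astype(float) - causal_offset) @ betas
        return G, score

    G0, s0 = draw_batch(batch)
    beta0 = _calibrate_intercept(s0, cfg.case_fraction)

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case = n_ctrl = 0
    drawn = 0
    G, score = G0, s0
    while True:
        drawn += len(G)
        p_case = 1.0 / (1.0 + np.exp(-(beta0 + score)))
        status = rng.random(len(G)) < p_case
        need_case = cfg.n_cases - n_case
        need_ctrl = cfg.n_controls - n_ctrl
        take_case = np.flatnonzero(status)[:need_case]
        take_ctrl = np.flatnonzero(~status)[:need_ctrl]
        cases.append(G[take_case])
        controls.append(G[take_ctrl])
        n_case += len(take_case)
        n_ctrl += len(take_ctrl)
        if n_case >= cfg.n_cases and n_ctrl >= cfg.n_controls:
            break
        if drawn >= max_draws:
            raise SimulationError(
                f"could not collect {cfg.n_cases}/{cfg.n_controls} cases/controls "
                f"within {max_draws} draws"
            )
        G, score = draw_batch(batch)

    genotypes = np.vstack(cases + controls)
    phenotypes = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
    )
    order = rng.permutation(n_target)
    genotypes = genotypes[order]
    phenotypes = phenotypes[order]

    if cfg.missing_rate > 0:
        mask = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[mask] = MISSING

    sample_meta = pd.DataFrame({"sample_id": [f"I{i + 1:06d}" for i in range(n_target)]})
    return GenotypeDataset(genotypes, phenotypes, snp_meta, sample_meta)


# ---------------------------------------------------------------------------
# functional tables
# ---------------------------------------------------------------------------

def simulate_functional_tables(
    cfg: SimulationConfig,
    snp_meta: pd.DataFrame,
    causal_snp_ids,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate eQTL and Regulome tables over the SNP universe of ``snp_meta``.

    Every SNP receives an eQTL p-value for its own gene (low-p mixture
    component with probability boosted by ``functional_enrichment_odds`` for
    causal SNPs) and a RegulomeDB-style category, with causal SNPs boosted
    into the strong-evidence 1a-2c group by the same odds.
    """
    rng = derive_rng(cfg.seed, 2)
    snp_ids = snp_meta["snp_id"].to_numpy()
    causal_ids = pd.Index(causal_snp_ids)
    unknown = causal_ids.difference(pd.Index(snp_ids))
    if len(unknown):
        raise DataError(f"causal SNP ids not in annotation: {list(unknown[:5])}")
    is_causal = np.isin(snp_ids, causal_ids.to_numpy())

    q = np.where(
        is_causal,
        _odds_boost(_EQTL_BACKGROUND_RATE, cfg.functional_enrichment_odds),
        _EQTL_BACKGROUND_RATE,
    )
    hit = rng.random(len(snp_ids)) < q
    pvals = np.where(
        hit, rng.uniform(0.0, 0.05, len(snp_ids)), rng.uniform(0.05, 1.0, len(snp_ids))
    )
    gene_col = (
        snp_meta["gene_id"].to_numpy() if "gene_id" in snp_meta.columns else np.repeat("NA", len(snp_ids))
    )
    eqtl = pd.DataFrame({"snp_id": snp_ids, "gene_id": gene_col, "pvalue": pvals})

    p_func = np.where(
        is_causal,
        _odds_boost(_REGULOME_FUNCTIONAL_RATE, cfg.functional_enrichment_odds),
        _REGULOME_FUNCTIONAL_RATE,
    )
    functional = rng.random(len(snp_ids)) < p_func
    cats = np.where(
        functional,
        rng.choice(_FUNCTIONAL_GROUP, size=len(snp_ids)),
        rng.choice(_NONFUNCTIONAL_GROUP, size=len(snp_ids)),
    )
    regulome = pd.DataFrame({"snp_id": snp_ids, "category": cats})
    return eqtl, regulome


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    genes: pd.DataFrame
    gene_sets: dict[str, list[str]]
    dataset: GenotypeDataset
    eqtl: pd.DataFrame
    regulome: pd.DataFrame

    @property
    def causal_pathways(self) -> list[str]:
        col = self.dataset.snp_meta["causal_pathway"]
        return sorted(c for c in col.unique() if c)

    @property
    def causal_snp_ids(self) -> list[str]:
        m = self.dataset.snp_meta
        return m.loc[m["is_causal"], "snp_id"].tolist()


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run annotation, genotype and functional-table simulation in one call."""
    annotation = simulate_annotation(cfg)
    ds = simulate_genotypes(cfg, annotation)
    causal_ids = ds.snp_meta.loc[ds.snp_meta["is_causal"], "snp_id"].tolist()
    eqtl, regulome = simulate_functional_tables(cfg, ds.snp_meta, causal_ids)
    return SimulatedStudy(cfg, annotation[0], annotation[1], ds, eqtl, regulome)
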