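"""Mutual-information mRmR feature selection and appearance rates.

The selection statistic is plug-in mutual information in bits between a
SNP's additive genotype (0/1/2) and the binary case-control label, with
missing genotypes pairwise-deleted and no pseudo-counts.  Greedy mRmR picks
the SNP maximizing relevance ``I(x; y)`` first, then repeatedly adds the
candidate maximizing either

* ``I(x; y) - mean_s I(x; s)``  (``difference`` criterion, MID), or
* ``I(x; y) / mean_s I(x; s)``  (``quotient`` criterion, MIQ)

over the already-selected set ``s``, breaking ties by candidate order
(callers pass columns in genomic (chrom, position, snp_id) order).

One resampling iteration runs mRmR on ``n_subsamples`` stratified 80%
subsamples of the selection set and keeps SNPs chosen in at least
``consensus_min`` runs; a SNP's appearance rate is the fraction of the
resampling iterations whose consensus set contained it.  For gene-level
reporting, appearance rates are summed over a gene's SNPs and normalized by
the gene's number of LD tag SNPs (greedy pruning at r-squared 0.50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MrmrConfig
from .errors import ClassBalanceError, DegenerateInputError, SelectionError

__all__ = [
    "mutual_information",
    "mrmr_select",
    "consensus_select",
    "SelectionTrace",
    "appearance_rates",
    "ld_r2",
    "greedy_tag_snps",
    "gene_appearance_rate",
]

logger = logging.getLogger(__name__)

_MISSING = -1


def _mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a joint contingency table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in bits between a genotype vector and a binary label.

    Entries where the genotype is missing (coded ``-1``) are
    pairwise-deleted.  Raises :class:`DegenerateInputError` if the label is
    constant after deletion.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    valid = (x != _MISSING) & (y != _MISSING)
    x, y = x[valid], y[valid]
    _, xi = np.unique(x, return_inverse=True)
    yvals, yi = np.unique(y, return_inverse=True)
    if len(yvals) < 2:
        raise DegenerateInputError("label vector is constant after pairwise deletion")
    nx, ny = xi.max() + 1, yi.max() + 1
    counts = np.bincount(ny * xi + yi, minlength=nx * ny)
    return _mi_from_counts(counts.reshape(nx, ny))


def _mi_from_counts_batch(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI (bits) for a batch of joint tables ``(p, a, b)``."""
    n = counts.sum(axis=(1, 2), keepdims=True).astype(float)
    n[n == 0] = 1.0
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    ind = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / ind), 0.0)
    return terms.sum(axis=(1, 2))


def _relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI of every column of X with y (pairwise deletion per column)."""
    n, p = X.shape
    x64 = X.astype(np.int64)
    code = 6 * np.arange(p) + 3 * y.astype(np.int64)[:, None] + x64
    counts = np.bincount(code[x64 != _MISSING], minlength=6 * p)
    return _mi_from_counts_batch(counts.reshape(p, 2, 3))


def _mi_columns(X: np.ndarray, j: int) -> np.ndarray:
    """MI of column j with every column of X."""
    n, p = X.shape
    x64 = X.astype(np.int64)
    xj = x64[:, j]
    code = 9 * np.arange(p) + 3 * xj[:, None] + x64
    valid = (x64 != _MISSING) & (xj != _MISSING)[:, None]
    counts = np.bincount(code[valid], minlength=9 * p)
    return _mi_from_counts_batch(counts.reshape(p, 3, 3))


def mrmr_select(X: np.ndarray, y: np.ndarray, cfg: MrmrConfig) -> list[int]:
    """Greedy mRmR selection; returns column indices in selection order.

    Selects ``min(cfg.k_features, n_columns)`` features.  Columns must
    already be in the deterministic genomic order used for tie-breaking.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] == 0:
        raise SelectionError("empty candidate pool")
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("both classes required for selection")
    p = X.shape[1]
    k = min(cfg.k_features, p)
    rel = _relevance(X, y)
    selected = [int(np.argmax(rel))]
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    available[selected[0]] = False
    while len(selected) < k:
        red_sum += _mi_columns(X, selected[-1])
        red_mean = red_sum / len(selected)
        if cfg.criterion == "difference":
            score = rel - red_mean
        else:
            score = rel / np.maximum(red_mean, 1e-12)
        score[~available] = -np.inf
        pick = int(np.argmax(score))  # argmax keeps lowest index on ties
        selected.append(pick)
        available[pick] = False
    return selected


def _stratified_take(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of a per-class ``fraction`` subsample (round half up)."""
    take = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_take = int(np.floor(fraction * len(idx) + 0.5))
        take.append(rng.permutation(idx)[:n_take])
    return np.sort(np.concatenate(take))


def consensus_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: MrmrConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[int], list[list[int]]]:
    """One resampling iteration's SNP set from subsampled mRmR runs.

    Runs :func:`mrmr_select` on ``cfg.n_subsamples`` stratified subsamples
    of ``(X, y)`` and returns ``(consensus, runs)`` where ``consensus`` is
    the sorted list of column indices chosen in at least
    ``cfg.consensus_min`` runs (may hold fewer than two entries — the
    caller's pathway-exclusion signal).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts = np.zeros(X.shape[1], dtype=np.int64)
    runs = []
    for _ in range(cfg.n_subsamples):
        idx = _stratified_take(np.asarray(y), cfg.subsample_fraction, rng)
        chosen = mrmr_select(X[idx], np.asarray(y)[idx], cfg)
        counts[chosen] += 1
        runs.append(chosen)
    consensus = [int(j) for j in np.flatnonzero(counts >= cfg.consensus_min)]
    return consensus, runs


# ---------------------------------------------------------------------------
# appearance rates
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Per-pathway record of the SNPs selected in each resampling iteration."""

    pathway_id: str
    iterations: list[tuple[str, ...]]

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def rates(self) -> dict[str, float]:
        return appearance_rates(self.iterations)

    def selection_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for snps in self.iterations:
            for s in snps:
                counts[s] = counts.get(s, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        counts = self.selection_counts()
        rows = [
            (self.pathway_id, snp, counts[snp] / self.n_iterations, counts[snp])
            for snp in sorted(counts)
        ]
        return pd.DataFrame(
            rows, columns=["pathway_id", "snp_id", "appearance_rate", "n_iterations_selected"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def appearance_rates(
    iteration_sets: Iterable[Iterable[str]], n_iterations: int | None = None
) -> dict[str, float]:
    """SNP -> (selections / iterations).  SNPs never selected are absent
    (their rate is 0 by definition)."""
    sets = [tuple(s) for s in iteration_sets]
    n = n_iterations if n_iterations is not None else len(sets)
    if n == 0:
        return {}
    counts: dict[str, int] = {}
    for snps in sets:
        for s in snps:
            counts[s] = counts.get(s, 0) + 1
    return {s: c / n for s, c in counts.items()}


# ---------------------------------------------------------------------------
# LD tagging and gene-level normalization
# ---------------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of additive genotype codes.

    A composite-LD surrogate computed on pairwise-complete entries;
    invariant to allele flips (``g -> 2 - g``).  Raises
    :class:`DegenerateInputError` if either vector is constant after
    deletion.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    valid = (g1 != _MISSING) & (g2 != _MISSING)
    a, b = g1[valid], g2[valid]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("correlation undefined for constant genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def greedy_tag_snps(
    genotypes: np.ndarray, r2_threshold: float = 0.5
) -> tuple[int, list[int]]:
    """Greedy haplotype-tag pruning within a gene.

    Scans columns in the given (genomic) order and keeps a SNP iff its
    r-squared with every previously kept SNP is below ``r2_threshold``.
    Monomorphic columns have undefined correlation and are treated as
    unlinked (kept).  Returns ``(tag_count, kept_indices)``.
    """
    G = np.asarray(genotypes)
    kept: list[int] = []
    for j in range(G.shape[1]):
        independent = True
        for t in kept:
            try:
                r2 = ld_r2(G[:, t], G[:, j])
            except DegenerateInputError:
                continue
            if r2 >= r2_threshold:
                independent = False
                break
        if independent:
            kept.append(j)
    return len(kept), kept


def gene_appearance_rate(
    snp_rates: Mapping[str, float],
    gene_to_snps: Mapping[str, Sequence[str]],
    tag_counts: Mapping[str, int],
) -> dict[str, float]:
    """Gene rate = (sum of its SNPs' appearance rates) / gene tag count.

    Genes with no SNPs are omitted with a warning.
    """
    out: dict[str, float] = {}
    for gene, snps in gene_to_snps.items():
        if not snps:
            logger.warning("gene %s has no SNPs; omitted from gene appearance rates", gene)
            continue
        tags = tag_counts[gene]
        if tags < 1:
            raise ValueError(f"gene {gene}: tag count must be >= 1")
        out[gene] = sum(snp_rates.get(s, 0.0) for s in snps) / tags
    return out
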