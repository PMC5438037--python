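"""Appearance-rate-based functional enrichment of selected SNPs.

SNPs that represent a pathway often (high appearance rate across the
resampling iterations) are hypothesized to be enriched for regulatory
function.  Two annotations are supported: *cis*-eQTL associations (the
statistic is the proportion of SNPs with an eQTL p-value below 0.05 for a
gene the SNP maps to) and RegulomeDB-style ordinal categories (the
statistic is a weighted mean score, monotone in evidence strength).

Candidate statistics are compared against a background sample — one value
per non-significant-pathway SNP set (or per random SNP set of equal size) —
with a two-sided one-sample t-test of the background values against the
candidate value, reporting direction (enriched/depleted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "REGULOME_CATEGORIES",
    "REGULOME_WEIGHTS",
    "quartile_bins",
    "eqtl_proportion",
    "regulome_weight",
    "weighted_regulome_score",
    "enrichment_test",
    "EnrichmentResult",
    "functional_report",
    "random_background_sets",
]

#: RegulomeDB-style ordinal categories, strongest regulatory evidence first.
REGULOME_CATEGORIES = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6", "7",
)

#: Declared monotone, evenly spaced weights (strong evidence -> high score).
#: Exposed as data so an alternative weighting can be substituted.
REGULOME_WEIGHTS: dict[str, float] = {
    cat: 7.0 - 0.5 * i for i, cat in enumerate(REGULOME_CATEGORIES)
}

_QUARTILES = (("Q1", 0.0, 0.25), ("Q2", 0.25, 0.50), ("Q3", 0.50, 0.75), ("Q4", 0.75, 1.0))


def quartile_bins(rates: Mapping[str, float]) -> dict[str, str]:
    """Bin SNPs into appearance-rate quartiles Q1-Q4.

    Boundaries are fixed and half-open on the left: Q1=(0, 0.25],
    Q2=(0.25, 0.50], Q3=(0.50, 0.75], Q4=(0.75, 1.0].  Rate-0 SNPs (never
    selected) fall in no bin.
    """
    out: dict[str, str] = {}
    for snp, rate in rates.items():
        if rate < 0 or rate > 1:
            raise ValueError(f"appearance rate for {snp!r} outside [0, 1]: {rate}")
        if rate == 0:
            continue
        for label, lo, hi in _QUARTILES:
            if lo < rate <= hi:
                out[snp] = label
                break
    return out


def eqtl_proportion(
    snps: Iterable[str],
    eqtl: pd.DataFrame,
    alpha: float = 0.05,
    snp_genes: Mapping[str, Iterable[str]] | None = None,
) -> float:
    """Fraction of the SNP set with a qualifying eQTL record (p < alpha).

    When ``snp_genes`` is given, only records for a gene the SNP maps to
    qualify; otherwise any record for the SNP counts.  SNPs absent from the
    table count as non-eQTL.
    """
    snp_list = list(dict.fromkeys(snps))
    if not snp_list:
        raise ValueError("eqtl_proportion: empty SNP set")
    hits = eqtl.loc[(eqtl["pvalue"] < alpha) & eqtl["snp_id"].isin(snp_list)]
    if snp_genes is not None:
        ok = [
            row.snp_id
            for row in hits.itertuples(index=False)
            if row.gene_id in set(snp_genes.get(row.snp_id, ()))
        ]
        qualifying = set(ok)
    else:
        qualifying = set(hits["snp_id"])
    return len(qualifying.intersection(snp_list)) / len(snp_list)


def regulome_weight(category: str, weights: Mapping[str, float] | None = None) -> float:
    """Weight of one RegulomeDB-style category (monotone in evidence).

    ``weights`` substitutes an alternative category->weight table.
    """
    table = REGULOME_WEIGHTS if weights is None else weights
    try:
        return table[category]
    except KeyError:
        raise ValueError(f"unknown Regulome category {category!r}") from None


def weighted_regulome_score(
    snps: Iterable[str],
    regulome: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Mean category weight over a SNP set (duplicates ignored).

    SNPs without a table entry score 0 (no regulatory evidence), matching
    the weakest declared category.
    """
    snp_list = list(dict.fromkeys(snps))
    if not snp_list:
        raise ValueError("weighted_regulome_score: empty SNP set")
    lookup = dict(zip(regulome["snp_id"], regulome["category"]))
    total = 0.0
    for s in snp_list:
        cat = lookup.get(s)
        total += regulome_weight(cat, weights) if cat is not None else 0.0
    return total / len(snp_list)


def enrichment_test(
    candidate: float, background: Sequence[float]
) -> tuple[float, str]:
    """One-sample t-test of the background sample against the candidate value.

    Returns ``(two-sided p, direction)`` with direction ``"enriched"`` when
    the candidate exceeds the background mean, else ``"depleted"``.
    """
    bg = np.asarray(background, dtype=float)
    if len(bg) < 2:
        raise DegenerateInputError("need >= 2 background values")
    if np.ptp(bg) == 0:
        raise DegenerateInputError("zero-variance background sample")
    _, p = sps.ttest_1samp(bg, popmean=float(candidate))
    direction = "enriched" if candidate > bg.mean() else "depleted"
    return float(p), direction


@dataclass
class EnrichmentResult:
    """One cell of the enrichment grid."""

    group: str
    annotation: str
    threshold: float
    statistic: float
    background_values: list[float]
    p: float
    flag: str  # enriched / depleted / NS / not-evaluable / degenerate-background


def _candidate_set(rates: Mapping[str, float], threshold: float) -> list[str]:
    return [s for s, r in rates.items() if r > threshold]


def functional_report(
    candidate_rates: Mapping[str, Mapping[str, float]],
    background_sets: Sequence[Iterable[str]],
    eqtl: pd.DataFrame,
    regulome: pd.DataFrame,
    thresholds: Sequence[float] = (0.50, 0.75),
    alpha: float = 0.05,
    sig_level: float = 0.05,
    snp_genes: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Enrichment grid over (pathway, threshold, annotation) cells.

    ``candidate_rates`` maps each candidate pathway to its SNP appearance
    rates; ``background_sets`` is a sequence of SNP sets (typically one per
    non-significant pathway) each contributing one background statistic.
    Cells with an empty candidate set are marked ``not-evaluable``;
    degenerate backgrounds are surfaced per cell.
    """
    stat_fns = {
        "eqtl": lambda snps: eqtl_proportion(snps, eqtl, alpha, snp_genes),
        "regulome": lambda snps: weighted_regulome_score(snps, regulome),
    }
    bg_sets = [list(dict.fromkeys(s)) for s in background_sets]
    rows: list[EnrichmentResult] = []
    for annotation, stat_fn in stat_fns.items():
        bg_values = [stat_fn(s) for s in bg_sets if s]
        for pid, rates in candidate_rates.items():
            for thr in thresholds:
                snps = _candidate_set(rates, thr)
                if not snps:
                    rows.append(
                        EnrichmentResult(pid, annotation, thr, float("nan"), bg_values, float("nan"), "not-evaluable")
                    )
                    continue
                stat = stat_fn(snps)
                try:
                    p, direction = enrichment_test(stat, bg_values)
                except DegenerateInputError:
                    rows.append(
                        EnrichmentResult(pid, annotation, thr, stat, bg_values, float("nan"), "degenerate-background")
                    )
                    continue
                flag = direction if p < sig_level else "NS"
                rows.append(EnrichmentResult(pid, annotation, thr, stat, bg_values, p, flag))
    return pd.DataFrame(
        [
            {
                "pathway": r.group,
                "annotation": r.annotation,
                "threshold": r.threshold,
                "statistic": r.statistic,
                "p": r.p,
                "flag": r.flag,
            }
            for r in rows
        ]
    )


def random_background_sets(
    snp_ids: Sequence[str], size: int, n_sets: int, rng: np.random.Generator | int = 0
) -> list[list[str]]:
    """Random SNP sets of equal size (the alternative background)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ids = np.asarray(snp_ids)
    if size > len(ids):
        raise ValueError("background set size exceeds SNP universe")
    return [list(rng.choice(ids, size=size, replace=False)) for _ in range(n_sets)]
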