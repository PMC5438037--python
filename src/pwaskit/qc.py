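"""Genotype quality control.

Filters run in a fixed order — user exclusion list, sample missingness, SNP
missingness, minor-allele frequency, Hardy-Weinberg exact test — with the
HWE test computed in controls only, since case genotypes can deviate from
equilibrium under a true association.  The exact test follows the standard
conditional-on-allele-counts construction: the p-value sums the
probabilities of all heterozygote counts whose conditional probability does
not exceed that of the observed table (no mid-p adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QcThresholds
from .dataset import GenotypeDataset
from .errors import EmptyDatasetError

__all__ = ["hwe_exact_test", "apply_qc", "QcReport"]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Conditional on the observed allele counts, heterozygote-count
    probabilities are computed by the stable ratio recurrence and the
    p-value is the summed probability of tables as extreme or more extreme
    (probability less than or equal to the observed table's).
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible heterozygote counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # log-space recurrence avoids overflow for large samples
    logp = np.empty(len(hets), dtype=float)
    logp[0] = 0.0
    for k in range(1, len(hets)):
        h = hets[k]  # from h-2 hets to h hets
        rare_hom = (n_rare - (h - 2)) // 2
        common_hom = n - (h - 2) - rare_hom
        logp[k] = logp[k - 1] + np.log(4.0 * rare_hom * common_hom) - np.log(h * (h - 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[(n_het - het_min) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    """Per-step removal counts from :func:`apply_qc`."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, step: str, removed: int, remaining: int) -> None:
        self.steps.append((step, removed, remaining))

    def removed(self, step: str) -> int:
        return next(r for s, r, _ in self.steps if s == step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "items_removed", "items_remaining"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _genotype_counts_controls(ds: GenotypeDataset) -> np.ndarray:
    """(n_snps, 3) genotype counts among controls, missing excluded."""
    g = ds.genotypes[ds.phenotypes == 0]
    counts = np.empty((ds.n_snps, 3), dtype=np.int64)
    for value in (0, 1, 2):
        counts[:, value] = (g == value).sum(axis=0)
    return counts


def apply_qc(
    ds: GenotypeDataset,
    thr: QcThresholds | None = None,
    exclude_samples=None,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the QC filter cascade and return the filtered dataset + report.

    ``exclude_samples`` is an optional iterable of sample IDs removed before
    any statistical filter (the hook for externally derived ancestry or
    relatedness exclusions).
    """
    thr = thr or QcThresholds()
    report = QcReport()

    if exclude_samples is not None:
        drop = set(exclude_samples)
        keep = ~ds.sample_ids.isin(drop).to_numpy()
        report.record("sample_exclusion_list", int((~keep).sum()), int(keep.sum()))
        ds = ds.subset(samples=np.flatnonzero(keep))

    keep_s = ds.sample_missingness() <= thr.sample_missing_max
    report.record("sample_missingness", int((~keep_s).sum()), int(keep_s.sum()))
    if not keep_s.any():
        raise EmptyDatasetError("sample-missingness filter removed every sample")
    ds = ds.subset(samples=np.flatnonzero(keep_s))

    keep_v = ds.snp_missingness() <= thr.snp_missing_max
    report.record("snp_missingness", int((~keep_v).sum()), int(keep_v.sum()))
    if not keep_v.any():
        raise EmptyDatasetError("SNP-missingness filter removed every SNP")
    ds = ds.subset(snps=np.flatnonzero(keep_v))

    maf = ds.minor_allele_frequency()
    keep_v = ~(maf < thr.maf_min)  # NaN-MAF (all-missing) SNPs were caught above
    report.record("maf", int((~keep_v).sum()), int(keep_v.sum()))
    if not keep_v.any():
        raise EmptyDatasetError("MAF filter removed every SNP")
    ds = ds.subset(snps=np.flatnonzero(keep_v))

    if thr.hwe_p_min > 0 and (ds.phenotypes == 0).any():
        counts = _genotype_counts_controls(ds)
        hwe_p = np.array([hwe_exact_test(*row) for row in counts])
        keep_v = hwe_p >= thr.hwe_p_min
    else:
        keep_v = np.ones(ds.n_snps, dtype=bool)
    report.record("hwe", int((~keep_v).sum()), int(keep_v.sum()))
    if not keep_v.any():
        raise EmptyDatasetError("HWE filter removed every SNP")
    ds = ds.subset(snps=np.flatnonzero(keep_v))

    return ds, report
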