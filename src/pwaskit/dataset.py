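"""Core in-memory container for case-control genotype data.

Genotypes are additive minor-allele counts in ``{0, 1, 2}`` stored as an
``int8`` sample x SNP matrix with ``-1`` marking missing calls.  Phenotypes
are ``1`` for cases and ``0`` for controls.  SNP and sample metadata ride on
pandas DataFrames aligned positionally with the matrix axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassBalanceError, DataError

MISSING = np.int8(-1)

SNP_META_COLUMNS = ["snp_id", "chrom", "position", "allele_a", "allele_b"]


@dataclass
class GenotypeDataset:
    """Sample x SNP additive genotype matrix with binary phenotype labels.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 array over ``{0, 1, 2}`` with ``-1``
        for missing.
    phenotypes
        ``(n_samples,)`` array, ``1`` = case, ``0`` = control.
    snp_meta
        One row per SNP; requires columns ``snp_id, chrom, position,
        allele_a, allele_b`` (extra columns, e.g. simulation truth, are kept).
    sample_meta
        One row per sample; requires column ``sample_id``.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DataError("genotypes must be a 2-D sample x SNP matrix")
        n, p = self.genotypes.shape
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)]})
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        if len(self.phenotypes) != n:
            raise DataError(f"phenotype length {len(self.phenotypes)} != {n} samples")
        if len(self.snp_meta) != p:
            raise DataError(f"snp_meta has {len(self.snp_meta)} rows for {p} SNPs")
        if len(self.sample_meta) != n:
            raise DataError(f"sample_meta has {len(self.sample_meta)} rows for {n} samples")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise DataError(f"snp_meta missing columns {missing_cols}")
        if self.snp_meta["snp_id"].duplicated().any():
            dup = self.snp_meta["snp_id"][self.snp_meta["snp_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate snp_id {dup!r}")
        if self.sample_meta["sample_id"].duplicated().any():
            dup = self.sample_meta["sample_id"][
                self.sample_meta["sample_id"].duplicated()
            ].iloc[0]
            raise DataError(f"duplicate sample_id {dup!r}")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise DataError("genotype values must be in {0, 1, 2} or -1 (missing)")
        if not np.isin(self.phenotypes, (0, 1)).all():
            raise DataError("phenotypes must be 0 (control) or 1 (case)")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> pd.Series:
        return self.snp_meta["snp_id"]

    @property
    def sample_ids(self) -> pd.Series:
        return self.sample_meta["sample_id"]

    def require_both_classes(self) -> None:
        """Raise unless cases and controls are both present."""
        if len(np.unique(self.phenotypes)) < 2:
            raise ClassBalanceError("dataset must contain both cases and controls")

    # -- subsetting -------------------------------------------------------
    def subset(self, samples=None, snps=None) -> "GenotypeDataset":
        """Positional subset along either axis (index arrays or bool masks)."""
        g = self.genotypes
        ph = self.phenotypes
        sm = self.sample_meta
        vm = self.snp_meta
        if samples is not None:
            samples = np.asarray(samples)
            g = g[samples, :]
            ph = ph[samples]
            sm = sm.iloc[samples]
        if snps is not None:
            snps = np.asarray(snps)
            g = g[:, snps]
            vm = vm.iloc[snps]
        return GenotypeDataset(g.copy(), ph.copy(), vm.copy(), sm.copy())

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP IDs (raises on unknown IDs)."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snp_meta["snp_id"])
        ids = pd.Index(snp_ids)
        unknown = ids.difference(lookup.index)
        if len(unknown):
            raise DataError(f"unknown SNP ids: {list(unknown[:5])}")
        return lookup.loc[ids].to_numpy()

    # -- summary statistics ----------------------------------------------
    def snp_missingness(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-SNP MAF over non-missing calls (folded to <= 0.5)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)
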