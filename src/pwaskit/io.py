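"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
PLINK text ``.ped``/``.map``
    Alleles per SNP; ``0 0`` encodes a missing call; ``.map`` positions are
    1-based and converted to the package's 0-based convention at this
    boundary.  On reading, the additive code counts the sample-minor allele
    (ties broken alphabetically), so orientation is data-driven as in PLINK.
TSV genotype matrix
    Header ``sample_id  phenotype  <snp ids...>``; values 0/1/2 with a
    configurable missing sentinel (default ``NA``).  Exact round-trip.
BED-like gene annotation
    Columns ``chrom  start  end  strand  gene_id`` (0-based, half-open).
GMT gene sets
    One pathway per line: ``pathway_id<TAB>description<TAB>gene...``.
eQTL / Regulome tables
    TSV with header ``snp_id  gene_id  pvalue`` / ``snp_id  category``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .errors import DataError, FormatError

__all__ = [
    "read_genotypes",
    "write_plink_text",
    "read_plink_text",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
    "read_eqtl_table",
    "read_regulome_table",
]


def read_genotypes(path: str | Path, format: str = "plink_text", **kwargs) -> GenotypeDataset:
    """Read a genotype dataset; ``format`` is ``plink_text`` or ``tsv_matrix``.

    For ``plink_text``, ``path`` is the shared prefix of ``<path>.ped`` and
    ``<path>.map``.
    """
    if format == "plink_text":
        return read_plink_text(path, **kwargs)
    if format == "tsv_matrix":
        return read_genotype_tsv(path, **kwargs)
    raise FormatError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def write_plink_text(ds: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (positions 1-based)."""
    prefix = Path(prefix)
    meta = ds.snp_meta
    with open(f"{prefix}.map", "w") as fh:
        for row in meta.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{int(row.position) + 1}\n")
    allele_a = meta["allele_a"].astype(str).to_numpy()
    allele_b = meta["allele_b"].astype(str).to_numpy()
    # genotype g = count of allele_b
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(ds.n_samples):
            pheno = 2 if ds.phenotypes[i] == 1 else 1
            fields = [str(ds.sample_ids.iloc[i]), str(ds.sample_ids.iloc[i]), "0", "0", "0", str(pheno)]
            g = ds.genotypes[i]
            for j in range(ds.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [allele_a[j], allele_a[j]]
                elif g[j] == 1:
                    fields += [allele_a[j], allele_b[j]]
                else:
                    fields += [allele_b[j], allele_b[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(prefix: str | Path) -> GenotypeDataset:
    """Read ``<prefix>.ped`` + ``<prefix>.map`` into a :class:`GenotypeDataset`."""
    prefix = Path(prefix)
    map_rows = []
    with open(f"{prefix}.map") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{prefix}.map: expected 4 columns", line=ln)
            try:
                pos = int(parts[3]) - 1  # to 0-based
            except ValueError:
                raise FormatError(f"{prefix}.map: unparseable position {parts[3]!r}", line=ln)
            map_rows.append((parts[0], parts[1], pos))
    n_snps = len(map_rows)
    sample_ids, phenotypes, raw_alleles = [], [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{prefix}.ped: expected {6 + 2 * n_snps} fields for {n_snps} "
                    f"mapped SNPs, got {len(parts)}",
                    line=ln,
                )
            sample_ids.append(parts[1])
            if parts[5] == "2":
                phenotypes.append(1)
            elif parts[5] == "1":
                phenotypes.append(0)
            else:
                raise FormatError(
                    f"{prefix}.ped: phenotype {parts[5]!r} is not case/control (2/1)",
                    line=ln,
                )
            raw_alleles.append(parts[6:])
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError(f"{prefix}.ped: duplicate sample IDs")
    alleles = np.array(raw_alleles, dtype=object).reshape(len(sample_ids), n_snps, 2)
    genotypes = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    allele_a_out, allele_b_out = [], []
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"{prefix}.ped: SNP {map_rows[j][1]} has >2 alleles")
        if len(uniq) == 0:
            allele_a_out.append("0")
            allele_b_out.append("0")
            continue
        if len(uniq) == 1:
            major, minor = uniq[0], None
        else:
            # minor = less frequent allele; alphabetical tie-break
            order = np.lexsort((uniq, counts))
            minor, major = uniq[order[0]], uniq[order[1]]
        allele_a_out.append(str(major))
        allele_b_out.append(str(minor) if minor is not None else str(major))
        valid = (col != "0").all(axis=1)
        if minor is None:
            genotypes[valid, j] = 0
        else:
            genotypes[valid, j] = (col == minor).sum(axis=1)[valid]
    snp_meta = pd.DataFrame(
        {
            "snp_id": [r[1] for r in map_rows],
            "chrom": [r[0] for r in map_rows],
            "position": [r[2] for r in map_rows],
            "allele_a": allele_a_out,
            "allele_b": allele_b_out,
        }
    )
    sample_meta = pd.DataFrame({"sample_id": sample_ids})
    return GenotypeDataset(genotypes, np.array(phenotypes), snp_meta, sample_meta)


# ---------------------------------------------------------------------------
# TSV genotype matrix
# ---------------------------------------------------------------------------

def write_genotype_tsv(ds: GenotypeDataset, path: str | Path, missing: str = "NA") -> None:
    g = ds.genotypes.astype(object)
    g[g == int(MISSING)] = missing
    df = pd.DataFrame(g, columns=ds.snp_ids.tolist())
    df.insert(0, "phenotype", ds.phenotypes)
    df.insert(0, "sample_id", ds.sample_ids.to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path, missing: str = "NA") -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[:2].tolist() != ["sample_id", "phenotype"]:
        raise FormatError(f"{path}: first columns must be sample_id, phenotype", line=1)
    snp_ids = df.columns[2:].tolist()
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    genotypes = np.full(raw.shape, MISSING, dtype=np.int8)
    mask = raw != missing
    try:
        genotypes[mask] = raw[mask].astype(np.int8)
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable genotype token ({exc})")
    if not np.isin(genotypes, (-1, 0, 1, 2)).all():
        raise FormatError(f"{path}: genotype values must be 0/1/2 or {missing!r}")
    phen = df["phenotype"].astype(int).to_numpy()
    snp_meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "0",
            "position": np.arange(len(snp_ids)),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeDataset(genotypes, phen, snp_meta, pd.DataFrame({"sample_id": df["sample_id"]}))


# ---------------------------------------------------------------------------
# Gene annotation (BED-like) and GMT gene sets
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", names=GENE_COLUMNS, dtype={"chrom": str})
    bad = genes[(genes["start"] < 0) | (genes["start"] >= genes["end"])]
    if len(bad):
        raise FormatError(f"{path}: invalid gene interval for {bad['gene_id'].iloc[0]!r}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return genes


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for pid, genes in gene_sets.items():
            desc = descriptions.get(pid, "na")
            fh.write("\t".join([pid, desc] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file to ``{pathway_id: [gene, ...]}`` (order preserved)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line needs id, description, >=1 gene", line=ln)
            pid = parts[0].strip()
            if pid in sets:
                raise FormatError(f"{path}: duplicate pathway id {pid!r}", line=ln)
            sets[pid] = [g.strip() for g in parts[2:] if g.strip()]
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


# ---------------------------------------------------------------------------
# Functional annotation tables
# ---------------------------------------------------------------------------

def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    need = {"snp_id", "gene_id", "pvalue"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: eQTL table needs columns {sorted(need)}")
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise FormatError(f"{path}: eQTL p-values must be in [0, 1]")
    return df


def read_regulome_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"snp_id", "category"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: regulome table needs columns {sorted(need)}")
    return df
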