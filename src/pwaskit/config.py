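"""Configuration dataclasses and YAML (de)serialization.

Each config validates itself on construction and raises
:class:`~pwaskit.errors.ConfigurationError` naming the offending field.
Count fields that accept either a single value or an inclusive ``(lo, hi)``
range (``snps_per_gene``, ``genes_per_pathway``) are normalized to tuples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "QcThresholds",
    "MrmrConfig",
    "ForestConfig",
    "RunConfig",
    "load_yaml",
    "dump_yaml",
]


def _as_range(value, name: str) -> tuple[int, int]:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        value = (value, value)
    try:
        lo, hi = int(value[0]), int(value[1])
    except (TypeError, ValueError, IndexError):
        raise ConfigurationError(f"{name}: expected a count or (lo, hi) pair, got {value!r}")
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"{name}: invalid range {value!r}")
    return lo, hi


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ConfigurationError(message)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic case-control GWAS generator.

    Defaults emulate a desk-scale version of a restricted-access
    schizophrenia case-control study: a thousand cases and controls, SNPs
    grouped into genes and genes into pathway gene sets, a couple of causal
    pathways carrying modest per-allele log-odds effects (the observed
    pathway odds ratios in such studies stay below ~1.35), block LD, light
    missingness, and a five-fold functional-label enrichment among causal
    SNPs.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_genes: int = 300
    snps_per_gene: int | tuple[int, int] = 3
    n_pathways: int = 50
    genes_per_pathway: int | tuple[int, int] = 4
    n_causal_pathways: int = 2
    causal_snps_per_pathway: int = 2
    effect_size_beta: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_r2: float = 0.5
    missing_rate: float = 0.01
    functional_enrichment_odds: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cases >= 1, "n_cases: must be >= 1")
        _require(self.n_controls >= 1, "n_controls: must be >= 1")
        _require(self.n_genes >= 1, "n_genes: must be >= 1")
        _require(self.n_pathways >= 1, "n_pathways: must be >= 1")
        self.snps_per_gene = _as_range(self.snps_per_gene, "snps_per_gene")
        self.genes_per_pathway = _as_range(self.genes_per_pathway, "genes_per_pathway")
        _require(
            self.genes_per_pathway[1] <= self.n_genes,
            "genes_per_pathway: cannot exceed n_genes",
        )
        _require(
            0 <= self.n_causal_pathways <= self.n_pathways,
            "n_causal_pathways: must be in [0, n_pathways]",
        )
        _require(
            self.causal_snps_per_pathway
            <= self.genes_per_pathway[0] * self.snps_per_gene[0],
            "causal_snps_per_pathway: cannot exceed genes_per_pathway * snps_per_gene",
        )
        lo, hi = self.maf_range
        _require(0 < lo <= hi <= 0.5, "maf_range: need 0 < lo <= hi <= 0.5")
        self.maf_range = (float(lo), float(hi))
        _require(0 <= self.ld_block_r2 < 1, "ld_block_r2: must be in [0, 1)")
        _require(0 <= self.missing_rate < 1, "missing_rate: must be in [0, 1)")
        _require(
            self.functional_enrichment_odds >= 1,
            "functional_enrichment_odds: must be >= 1",
        )

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_samples


@dataclass
class QcThresholds:
    """Per-SNP / per-sample quality-control thresholds.

    Defaults follow the conventional community GWAS QC protocol values;
    Hardy-Weinberg is tested in controls only.
    """

    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.02
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "sample_missing_max", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            _require(0 <= v <= 1, f"{name}: must be in [0, 1]")


@dataclass
class MrmrConfig:
    """Subsampled mRmR consensus selection parameters.

    Ten 80% stratified subsamples of the selection set each run greedy mRmR
    for ``k_features``; SNPs chosen in at least ``consensus_min`` runs form
    the iteration's SNP set.
    """

    k_features: int = 30
    n_subsamples: int = 10
    subsample_fraction: float = 0.8
    consensus_min: int = 5
    criterion: str = "difference"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.k_features >= 1, "k_features: must be >= 1")
        _require(self.n_subsamples >= 1, "n_subsamples: must be >= 1")
        _require(0 < self.subsample_fraction <= 1, "subsample_fraction: must be in (0, 1]")
        _require(
            1 <= self.consensus_min <= self.n_subsamples,
            "consensus_min: must be in [1, n_subsamples]",
        )
        _require(
            self.criterion in ("difference", "quotient"),
            "criterion: must be 'difference' or 'quotient'",
        )


@dataclass
class ForestConfig:
    """Random-forest parameters, pinned explicitly (library defaults drift)."""

    n_trees: int = 500
    features_per_split: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_trees >= 1, "n_trees: must be >= 1")
        _require(
            self.features_per_split in ("sqrt", "log2", "all"),
            "features_per_split: must be one of 'sqrt', 'log2', 'all'",
        )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (file paths + stage configs)."""

    genotypes: str | None = None
    genotype_format: str = "plink_text"
    snp_meta: str | None = None  # coordinates for tsv_matrix genotypes
    annotation: str | None = None
    gene_sets: str | None = None
    eqtl: str | None = None
    regulome: str | None = None
    exclude_pathways: list[str] = field(default_factory=list)
    exclude_samples: str | None = None
    validation_genotypes: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    mrmr: MrmrConfig = field(default_factory=MrmrConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    window5: int = 2000
    window3: int = 500
    n_iterations: int = 100
    split_fraction: float = 0.8
    bh_alpha: float = 0.05
    master_seed: int = 0
    output_dir: str = "pwas_out"

    def __post_init__(self) -> None:
        _require(self.n_iterations >= 1, "n_iterations: must be >= 1")
        _require(0 < self.bh_alpha < 1, "bh_alpha: must be in (0, 1)")
        _require(0 < self.split_fraction < 1, "split_fraction: must be in (0, 1)")
        _require(self.window5 >= 0 and self.window3 >= 0, "windows: must be >= 0")
        if isinstance(self.qc, dict):
            self.qc = QcThresholds(**self.qc)
        if isinstance(self.mrmr, dict):
            self.mrmr = MrmrConfig(**self.mrmr)
        if isinstance(self.forest, dict):
            self.forest = ForestConfig(**self.forest)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_yaml(cfg: Any, path: str | Path) -> None:
    """Write any pwaskit config dataclass to a YAML file."""
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def load_yaml(cls: type, path: str | Path):
    """Load a config dataclass of type ``cls`` from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigurationError(f"{path}: unknown fields {sorted(unknown)}")
    return cls(**raw)
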