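"""One-call convenience workflows built from the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ForestConfig, MrmrConfig, QcThresholds, SimulationConfig
from .dataset import GenotypeDataset
from .pathways import PathwaySnpPool, assign_snps_to_genes, build_pathway_pools
from .qc import QcReport, apply_qc
from .selection import SelectionTrace
from .simulate import SimulatedStudy, simulate_study
from .stats import PathwayResult, run_pwas

__all__ = ["SyntheticPwasRun", "run_synthetic_pwas"]


@dataclass
class SyntheticPwasRun:
    """Everything produced by one simulate -> qc -> map -> associate run."""

    study: SimulatedStudy
    dataset: GenotypeDataset  # post-QC discovery cohort
    qc_report: QcReport
    mapping: pd.DataFrame
    pools: list[PathwaySnpPool]
    results: list[PathwayResult]
    traces: dict[str, SelectionTrace]

    @property
    def causal_pathways(self) -> list[str]:
        return self.study.causal_pathways


def run_synthetic_pwas(
    sim: SimulationConfig,
    *,
    mrmr: MrmrConfig | None = None,
    forest: ForestConfig | None = None,
    qc: QcThresholds | None = None,
    n_iterations: int = 100,
    master_seed: int = 0,
) -> SyntheticPwasRun:
    """Simulate a study and run the full pathway association pipeline on it."""
    study = simulate_study(sim)
    ds, report = apply_qc(study.dataset, qc or QcThresholds())
    mapping = assign_snps_to_genes(ds.snp_meta, study.genes)
    pools = build_pathway_pools(mapping, study.gene_sets)
    results, traces = run_pwas(
        pools,
        ds,
        mrmr=mrmr,
        forest=forest,
        n_iterations=n_iterations,
        master_seed=master_seed,
    )
    return SyntheticPwasRun(study, ds, report, mapping, pools, results, traces)
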