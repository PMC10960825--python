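"""End-to-end orchestration: preprocessing -> repeated sGCCA ->
consensus network -> module evaluation, with all randomness derived
from one master seed."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .consensus import (
    accumulate_cooccurrence,
    build_consensus_network,
    extract_consensus_modules,
)
from .containers import ModuleRecord, MultiOmicDataset, PipelineConfig
from .evaluation import evaluate_module
from .preprocess import RemovalReport, preprocess_table
from . import io as _io

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "preprocess_dataset", "run_pipeline", "stage_seeds"]


@dataclasses.dataclass
class PipelineResult:
    dataset: MultiOmicDataset  # preprocessed
    network: nx.Graph
    modules: list[ModuleRecord]
    removal_report: RemovalReport
    config: PipelineConfig

    @property
    def disease_associated(self) -> list[ModuleRecord]:
        return [
            m for m in self.modules
            if m.evaluation is not None and m.evaluation.is_disease_associated
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_modules_tsv(self.modules, outdir / "modules.tsv")
        _io.write_network(self.network, outdir / "network.tsv", outdir / "network.graphml")
        _io.write_evaluations_json(self.modules, outdir / "evaluation.json")
        self.removal_report.to_frame().to_csv(outdir / "removed_features.tsv", sep="\t", index=False)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Independent child seeds per stochastic stage.

    Spawning from one SeedSequence keeps stages independent: changing how
    many null modules are drawn cannot perturb the subsampling stream.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.generate_state(4) % (2**31 - 1)
    return {
        "preprocess": int(children[0]),
        "subsample": int(children[1]),
        "null": int(children[2]),
        "baseline": int(children[3]),
    }


def preprocess_dataset(
    dataset: MultiOmicDataset, config: PipelineConfig, seed: Optional[int] = None
) -> tuple[MultiOmicDataset, RemovalReport]:
    """Apply the shared preprocessing to every omic table of the dataset."""
    if seed is None:
        seed = stage_seeds(config.seed)["preprocess"]
    report = RemovalReport()
    tables = []
    for om in dataset.omics:
        table, rep, _cmap = preprocess_table(
            om,
            min_prevalence=config.min_prevalence,
            min_mean_abundance=config.min_mean_abundance,
            collinearity_threshold=config.collinearity_threshold,
            pseudocount=config.pseudocount,
            exclusion_list=config.exclusion_list,
            seed=seed,
        )
        report.extend(rep)
        tables.append(table)
    out = MultiOmicDataset(omics=tables, labels=dataset.labels, dataset_id=dataset.dataset_id)
    return out, report


def run_pipeline(
    dataset: MultiOmicDataset,
    config: Optional[PipelineConfig] = None,
    preprocessed: bool = False,
) -> PipelineResult:
    """Run the full module-discovery pipeline on one dataset.

    Stages: preprocessing (unless ``preprocessed``), repeated sGCCA over
    stratified subsamples, consensus-network construction at the ``edge``
    threshold, connected-component extraction, and evaluation of every
    consensus module against random null modules. Fully deterministic
    under ``config.seed``.
    """
    config = config or PipelineConfig()
    seeds = stage_seeds(config.seed)
    report = RemovalReport()
    if not preprocessed:
        try:
            dataset, report = preprocess_dataset(dataset, config, seeds["preprocess"])
        except Exception as exc:
            raise RuntimeError(f"preprocessing stage failed: {exc}") from exc

    try:
        counts = accumulate_cooccurrence(dataset, config, seed=seeds["subsample"])
    except Exception as exc:
        raise RuntimeError(f"subsampled sGCCA stage failed: {exc}") from exc

    try:
        network = build_consensus_network(counts, config.edge)
        modules = extract_consensus_modules(network, counts.feature_omic)
    except Exception as exc:
        raise RuntimeError(f"consensus stage failed: {exc}") from exc
    logger.info("found %d consensus modules", len(modules))

    rng = np.random.default_rng(seeds["null"])
    for module in modules:
        try:
            module.evaluation = evaluate_module(
                dataset,
                module,
                n_null=config.n_null,
                rng=rng,
                auc_threshold=config.auc_threshold,
                exceedance_rule=config.exceedance_rule,
                absolute_rho=config.absolute_rho,
            )
        except Exception as exc:
            raise RuntimeError(f"evaluation stage failed on {module.module_id}: {exc}") from exc

    return PipelineResult(
        dataset=dataset,
        network=network,
        modules=modules,
        removal_report=report,
        config=config,
    )
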