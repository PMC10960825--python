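"""Consensus module discovery over repeated data subsamples.

The sGCCA fit is repeated on random subsamples of the data (by default
100 runs, each on 80% of the samples via stratified 5-fold partitions).
Feature pairs that land in the same putative module in at least an
``edge`` fraction of runs (default 0.8) are connected in the consensus
network; connected components with >= 2 nodes are the consensus modules.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .containers import MultiOmicDataset, PipelineConfig, ModuleRecord
from .preprocess import standardize_block
from .sgcca import encode_label_block, extract_putative_modules, fit_sgcca, make_design

logger = logging.getLogger(__name__)

__all__ = [
    "CoOccurrenceCounts",
    "draw_subsamples",
    "accumulate_cooccurrence",
    "build_consensus_network",
    "extract_consensus_modules",
]


@dataclasses.dataclass
class CoOccurrenceCounts:
    """Number of subsample runs in which each feature pair shared a module."""

    total_runs: int
    pair_counts: dict[tuple[str, str], int]
    feature_omic: dict[str, str]

    def frequency(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return self.pair_counts.get(key, 0) / self.total_runs


def draw_subsamples(
    n_samples: int,
    labels: Sequence[int],
    nfol: int,
    nrep: int,
    seed: int,
) -> list[np.ndarray]:
    """Stratified leave-one-fold-out subsample index sets.

    Each repetition partitions the samples into ``nfol`` label-stratified
    folds; each run trains on ``nfol - 1`` folds, i.e. an
    ``(nfol-1)/nfol`` fraction. ``nrep`` total runs are drawn round-robin
    across as many fresh partitions as needed.
    """
    if nfol < 2:
        raise ValueError("nfol must be >= 2")
    y = np.asarray(labels)
    subsets: list[np.ndarray] = []
    partition_seed = np.random.SeedSequence(seed)
    n_partitions = int(np.ceil(nrep / nfol))
    child_seeds = partition_seed.generate_state(n_partitions)
    for p in range(n_partitions):
        skf = StratifiedKFold(
            n_splits=nfol, shuffle=True, random_state=int(child_seeds[p] % (2**31 - 1))
        )
        for train_idx, _test_idx in skf.split(np.zeros(n_samples), y):
            subsets.append(np.sort(train_idx))
            if len(subsets) == nrep:
                return subsets
    return subsets


def accumulate_cooccurrence(
    dataset: MultiOmicDataset,
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> CoOccurrenceCounts:
    """Run sGCCA on every subsample and count within-module feature pairs.

    Each block is standardized on the subsample only (no information from
    held-out samples leaks into the fit). A pair that co-occurs in more
    than one component of the same run still counts once for that run.
    """
    if seed is None:
        seed = config.seed
    y = dataset.labels.to_numpy()
    subsets = draw_subsamples(dataset.n_samples, y, config.nfol, config.nrep, seed)
    keep_map = config.keep_map(dataset.omic_ids)
    keep = [keep_map[o] for o in dataset.omic_ids]
    design = make_design(len(dataset.omics), config.des, with_label=True)
    block_values = [om.values for om in dataset.omics]
    block_features = [om.feature_ids for om in dataset.omics]

    pair_counts: dict[tuple[str, str], int] = {}
    total_runs = 0
    for run_idx, idx in enumerate(subsets):
        try:
            blocks = []
            for X in block_values:
                sub = X[idx]
                sd = sub.std(axis=0, ddof=1)
                # features constant within this subsample carry no signal here;
                # standardize them to zero rather than failing the run
                safe_sd = np.where(sd > 0, sd, 1.0)
                Z = (sub - sub.mean(axis=0)) / safe_sd
                Z[:, sd == 0] = 0.0
                blocks.append(Z)
            ylab = encode_label_block(y[idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_sgcca(
                    blocks,
                    design,
                    keep,
                    ncomp=config.ncomp,
                    tol=config.tol,
                    max_iter=config.max_iter,
                    label_block=ylab,
                    block_feature_ids=block_features,
                    block_names=dataset.omic_ids,
                    sparsity_mode=config.sparsity_mode,
                )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("subsample run %d failed and was skipped: %s", run_idx, exc)
            continue
        total_runs += 1
        run_pairs: set[tuple[str, str]] = set()
        for module in extract_putative_modules(model):
            feats = sorted(f for _, f in module.members)
            run_pairs.update(combinations(feats, 2))
        for pair in run_pairs:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1

    if total_runs == 0:
        raise RuntimeError("every subsample run failed; no co-occurrence counts")
    return CoOccurrenceCounts(
        total_runs=total_runs,
        pair_counts=pair_counts,
        feature_omic=dataset.feature_omic_map(),
    )


def build_consensus_network(counts: CoOccurrenceCounts, edge: float = 0.8) -> nx.Graph:
    """Undirected graph linking pairs with co-occurrence frequency >= edge."""
    if counts.total_runs <= 0:
        raise ValueError("total_runs must be positive")
    if not (0 < edge <= 1):
        raise ValueError("edge threshold must be in (0, 1]")
    g = nx.Graph()
    for (a, b), c in counts.pair_counts.items():
        freq = c / counts.total_runs
        if freq >= edge:
            g.add_edge(a, b, weight=freq)
    for node in g.nodes:
        g.nodes[node]["omic"] = counts.feature_omic.get(node, node.split(":", 1)[0])
    return g


def extract_consensus_modules(graph: nx.Graph, feature_omic: Optional[dict[str, str]] = None) -> list[ModuleRecord]:
    """Connected components of size >= 2, largest first (lexicographic ties)."""
    comps = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c))
    records = []
    for i, comp in enumerate(comps):
        omic_of = lambda f: (
            feature_omic[f] if feature_omic else graph.nodes[f].get("omic", f.split(":", 1)[0])
        )
        members = [(omic_of(f), f) for f in comp]
        edges = [
            (a, b, float(graph.edges[a, b].get("weight", 1.0)))
            for a, b in graph.edges(comp)
            if a in comp and b in comp
        ]
        edges = sorted({(min(a, b), max(a, b), w) for a, b, w in edges})
        records.append(ModuleRecord(module_id=f"module{i:02d}", members=members, edges=edges))
    return records
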