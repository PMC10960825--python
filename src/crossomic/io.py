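"""Readers and writers for the on-disk formats.

Feature tables are tab-separated with samples in rows (first column =
sample id, header = feature ids); metadata is a TSV with a sample-id
column and a label column. Outputs: modules.tsv, an edge-list TSV and
GraphML for the consensus network, evaluation.json, and the removal
report TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import (
    ABUNDANCE_OMICS,
    MultiOmicDataset,
    ModuleRecord,
    OmicTable,
    PipelineConfig,
    ScaleState,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "align_samples",
    "read_config",
    "write_modules_tsv",
    "write_network",
    "write_evaluations_json",
]


def read_feature_table(path: str | Path, omic_id: str) -> OmicTable:
    """Read a samples × features TSV into an :class:`OmicTable`.

    Feature ids are namespaced as ``"<omic_id>:<name>"`` unless already
    prefixed, so identifiers never collide across omics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty feature table")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups[:5]}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric column(s) {non_numeric[:5].tolist()}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values present")
    df.index = df.index.astype(str)
    df.columns = [
        c if str(c).startswith(f"{omic_id}:") else f"{omic_id}:{c}" for c in df.columns
    ]
    if omic_id in ABUNDANCE_OMICS and (df.to_numpy() < 0).any():
        logger.warning("%s: negative values in %s table; abundances are expected non-negative", path, omic_id)
    return OmicTable(omic_id=omic_id, data=df, scale_state=ScaleState.RAW)


def write_feature_table(table: OmicTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees bit-exact float round-trips
    table.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_metadata(
    path: str | Path,
    label_column: str,
    case_value: str,
    sample_column: Optional[str] = None,
) -> pd.Series:
    """Read the binary phenotype: 1 where label == case_value, else 0.

    Samples with a missing label are dropped (logged). The first column
    is the sample id unless ``sample_column`` names another one.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if sample_column is None:
        sample_column = df.columns[0]
    for col in (sample_column, label_column):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} not found")
    df = df.set_index(sample_column)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    missing = df[label_column].isna()
    if missing.any():
        logger.info("%s: dropped %d samples with missing label", path, int(missing.sum()))
        df = df[~missing]
    labels = (df[label_column] == case_value).astype(int)
    labels.index = labels.index.astype(str)
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(
            f"{path}: need >= 2 samples per class, got {counts.to_dict()} "
            f"(case_value={case_value!r})"
        )
    labels.name = "label"
    return labels


def align_samples(
    omics: Sequence[OmicTable],
    labels: pd.Series,
    dataset_id: str = "dataset",
) -> MultiOmicDataset:
    """Intersect sample ids across omics and metadata; sort for determinism."""
    shared = set(labels.index)
    for om in omics:
        shared &= set(om.sample_ids)
    if not shared:
        raise ValueError("no samples shared by all omic tables and the metadata")
    order = sorted(shared)
    dropped = {om.omic_id: om.n_samples - len(order) for om in omics}
    if any(dropped.values()):
        logger.info("align_samples dropped per omic: %s", dropped)
    aligned = [om.with_data(om.data.loc[order]) for om in omics]
    return MultiOmicDataset(omics=aligned, labels=labels.loc[order], dataset_id=dataset_id)


def read_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def write_modules_tsv(modules: Sequence[ModuleRecord], path: str | Path) -> None:
    """modules.tsv: module_id, omic, feature, node degree in the module."""
    rows = []
    for m in modules:
        degree = {f: 0 for f in m.feature_ids}
        for a, b, _w in m.edges:
            degree[a] += 1
            degree[b] += 1
        for omic, feat in m.members:
            rows.append((m.module_id, omic, feat, degree[feat]))
    df = pd.DataFrame(rows, columns=["module_id", "omic", "feature", "degree"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_network(graph: nx.Graph, tsv_path: str | Path, graphml_path: Optional[str | Path] = None) -> None:
    rows = sorted(
        (min(a, b), max(a, b), float(d.get("weight", 1.0))) for a, b, d in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "frequency"])
    Path(tsv_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)


def write_evaluations_json(modules: Sequence[ModuleRecord], path: str | Path) -> None:
    payload = {}
    for m in modules:
        entry: dict = {
            "members": [list(t) for t in m.members],
            "n_features": len(m),
            "omic_counts": m.omic_counts,
        }
        if m.evaluation is not None:
            entry.update(m.evaluation.to_dict())
        payload[m.module_id] = entry
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
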