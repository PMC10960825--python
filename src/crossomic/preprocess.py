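"""Shared preprocessing of omic feature tables.

Taxonomic and pathway profiles are converted to relative abundances by
total sum scaling; metabolite intensities are log-transformed. Constant
and rare features are removed (non-zero in fewer than 15% of samples, or
— for compositional omics — mean relative abundance below 0.005%).
Extremely collinear features (|Spearman| > 0.99 under complete linkage)
are collapsed to a single randomly chosen representative, since such
near-duplicates usually reflect technical redundancy rather than biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .containers import ABUNDANCE_OMICS, INTENSITY_OMICS, OmicTable, ScaleState

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityClusterMap",
    "RemovalReport",
    "tss_normalize",
    "log_transform",
    "filter_features",
    "exclude_features",
    "cluster_collinear",
    "standardize_block",
    "preprocess_table",
]


@dataclass
class RemovalReport:
    """Per-feature removal log: feature, omic, reason."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, feature: str, omic: str, reason: str) -> None:
        self.rows.append((feature, omic, reason))

    def extend(self, other: "RemovalReport") -> None:
        self.rows.extend(other.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["feature", "omic", "reason"])


@dataclass
class CollinearityClusterMap:
    """Clusters of near-duplicate features and their chosen representatives."""

    clusters: dict[str, list[str]]  # representative -> all members (incl. rep)
    threshold: float
    seed: int

    def collapsed_features(self) -> list[str]:
        return [m for rep, members in self.clusters.items() for m in members if m != rep]


def tss_normalize(table: OmicTable) -> OmicTable:
    """Total-sum-scale each sample's profile to relative abundances."""
    if table.scale_state != ScaleState.RAW:
        raise ValueError(f"omic {table.omic_id!r}: TSS expects raw values, got {table.scale_state.value}")
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"omic {table.omic_id!r}: sample(s) with zero total abundance: "
            f"{zero.index[:5].tolist()}"
        )
    return table.with_data(table.data.div(sums, axis=0), ScaleState.RELATIVE)


def log_transform(table: OmicTable, pseudocount: Optional[float] = None) -> OmicTable:
    """Natural-log transform intensities: x -> ln(x + pseudocount).

    With ``pseudocount=None`` each column uses half its minimum positive
    value, which preserves the dynamic range of sparse metabolites. A
    column of all zeros falls back to pseudocount 1 (log stays 0).
    """
    if table.scale_state not in (ScaleState.RAW, ScaleState.RELATIVE):
        raise ValueError(f"omic {table.omic_id!r}: log-transform expects raw values")
    vals = table.values
    if (vals < 0).any():
        raise ValueError(f"omic {table.omic_id!r}: negative intensities cannot be log-transformed")
    if pseudocount is None:
        pc = np.empty(vals.shape[1])
        for j in range(vals.shape[1]):
            pos = vals[:, j][vals[:, j] > 0]
            pc[j] = pos.min() / 2.0 if len(pos) else 1.0
    else:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        pc = np.full(vals.shape[1], float(pseudocount))
    out = pd.DataFrame(np.log(vals + pc), index=table.data.index, columns=table.data.columns)
    return table.with_data(out, ScaleState.LOG)


def filter_features(
    table: OmicTable,
    min_prevalence: float = 0.15,
    min_mean_abundance: float = 5e-5,
    *,
    prevalence_reference: Optional[OmicTable] = None,
) -> tuple[OmicTable, RemovalReport]:
    """Drop constant and rare features.

    A feature is rare when non-zero in fewer than ``min_prevalence`` of
    samples, or — for compositional omics (T/P, in relative scale) — when
    its mean relative abundance is below ``min_mean_abundance``. For
    log-transformed metabolite tables, prevalence is assessed on
    ``prevalence_reference`` (the raw intensities) when given, since the
    pseudocount removes zeros.
    """
    report = RemovalReport()
    vals = table.values
    prev_vals = prevalence_reference.values if prevalence_reference is not None else vals
    if prev_vals.shape != vals.shape:
        raise ValueError("prevalence_reference shape differs from table")

    keep_mask = np.ones(table.n_features, dtype=bool)
    nonzero_frac = (prev_vals != 0).mean(axis=0)
    constant = np.ptp(vals, axis=0) == 0
    is_abundance = table.omic_id in ABUNDANCE_OMICS and table.scale_state == ScaleState.RELATIVE
    mean_ab = vals.mean(axis=0)

    for j, feat in enumerate(table.feature_ids):
        if constant[j]:
            keep_mask[j] = False
            report.add(feat, table.omic_id, "constant")
        elif nonzero_frac[j] < min_prevalence:
            keep_mask[j] = False
            report.add(feat, table.omic_id, "low_prevalence")
        elif is_abundance and mean_ab[j] < min_mean_abundance:
            keep_mask[j] = False
            report.add(feat, table.omic_id, "low_abundance")

    if not keep_mask.any():
        raise ValueError(f"omic {table.omic_id!r}: all features removed by filtering")
    kept = table.with_data(table.data.loc[:, keep_mask])
    return kept, report


def exclude_features(table: OmicTable, exclusion_list: Iterable[str]) -> tuple[OmicTable, RemovalReport]:
    """Drop features by id (e.g. non-bacterial pathways); absent ids are logged."""
    report = RemovalReport()
    excl = set(exclusion_list)
    if not excl:
        return table, report
    present = [f for f in table.feature_ids if f in excl]
    absent = excl - set(table.feature_ids)
    if absent:
        logger.warning(
            "omic %s: %d exclusion ids not present (e.g. %s)",
            table.omic_id, len(absent), sorted(absent)[:3],
        )
    if not present:
        return table, report
    for f in present:
        report.add(f, table.omic_id, "excluded")
    remaining = table.data.drop(columns=present)
    if remaining.shape[1] == 0:
        raise ValueError(f"omic {table.omic_id!r}: exclusion list removed every feature")
    return table.with_data(remaining), report


def cluster_collinear(
    table: OmicTable,
    threshold: float = 0.99,
    seed: int = 0,
    method: str = "spearman",
) -> tuple[OmicTable, CollinearityClusterMap, RemovalReport]:
    """Collapse near-duplicate features (complete-linkage |rho| > threshold).

    Complete linkage guarantees every within-cluster pair exceeds the
    threshold. One member per cluster, chosen uniformly at random under
    ``seed``, is kept as representative.
    """
    report = RemovalReport()
    n_feat = table.n_features
    if n_feat < 2:
        return table, CollinearityClusterMap({}, threshold, seed), report

    if method == "spearman":
        rho = spearmanr(table.values).statistic
        if np.isscalar(rho):  # spearmanr collapses 2-column input to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
    elif method == "pearson":
        rho = np.corrcoef(table.values, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rho = np.nan_to_num(np.asarray(rho), nan=0.0)

    # complete linkage on 1 - |rho|; cut so merged clusters have all
    # pairwise |rho| strictly above the threshold
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    assign = fcluster(z, t=(1.0 - threshold) - 1e-12, criterion="distance")

    rng = np.random.default_rng(seed)
    clusters: dict[str, list[str]] = {}
    feats = np.asarray(table.feature_ids)
    drop: list[str] = []
    for cid in np.unique(assign):
        members = feats[assign == cid].tolist()
        if len(members) < 2:
            continue
        rep = members[int(rng.integers(len(members)))]
        clusters[rep] = members
        for m in members:
            if m != rep:
                drop.append(m)
                report.add(m, table.omic_id, f"collinear_with:{rep}")
    out = table.with_data(table.data.drop(columns=drop)) if drop else table
    return out, CollinearityClusterMap(clusters, threshold, seed), report


def standardize_block(
    matrix: np.ndarray,
    means: Optional[np.ndarray] = None,
    sds: Optional[np.ndarray] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Center and scale columns to mean 0, SD 1 (sample SD, ddof=1).

    Reference ``means``/``sds`` (e.g. computed on a training subsample)
    may be supplied; otherwise they come from ``matrix`` itself.
    """
    X = np.asarray(matrix, dtype=float)
    if means is None:
        means = X.mean(axis=0)
    if sds is None:
        sds = X.std(axis=0, ddof=1)
    zero = np.asarray(sds) <= 0
    if zero.any():
        if feature_names is not None:
            bad = [feature_names[j] for j in np.flatnonzero(zero)[:5]]
        else:
            bad = np.flatnonzero(zero)[:5].tolist()
        raise ValueError(f"cannot standardize constant column(s): {bad}")
    return (X - means) / sds


def preprocess_table(
    table: OmicTable,
    min_prevalence: float = 0.15,
    min_mean_abundance: float = 5e-5,
    collinearity_threshold: float = 0.99,
    pseudocount: Optional[float] = None,
    exclusion_list: Iterable[str] = (),
    seed: int = 0,
) -> tuple[OmicTable, RemovalReport, CollinearityClusterMap]:
    """Full preprocessing of one raw omic table.

    Compositional omics: TSS -> rare/abundance filter -> exclusion ->
    collinearity collapse. Intensity omics: log-transform -> prevalence
    filter (prevalence judged on the raw zeros) -> exclusion ->
    collinearity collapse.
    """
    report = RemovalReport()
    if table.omic_id in ABUNDANCE_OMICS:
        work = tss_normalize(table)
        work, rep = filter_features(work, min_prevalence, min_mean_abundance)
        report.extend(rep)
    else:
        raw = table
        work = log_transform(table, pseudocount)
        raw_aligned = raw.with_data(raw.data[work.feature_ids])
        work, rep = filter_features(
            work, min_prevalence, min_mean_abundance, prevalence_reference=raw_aligned
        )
        report.extend(rep)
    work, rep = exclude_features(work, exclusion_list)
    report.extend(rep)
    work, cmap, rep = cluster_collinear(work, collinearity_threshold, seed)
    report.extend(rep)
    return work, report, cmap
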