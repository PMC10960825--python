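"""Synthetic multi-omic datasets with planted, label-associated modules.

Each planted module m is driven by a latent factor

    z_m = alpha_m * (label - 0.5) * 2 + N(0, 1)

shared by all of the module's features across omics; a planted feature's
latent value is ``beta * z_m + sigma * N(0, 1)``, so within-module
correlations are ~ beta^2 / (beta^2 + sigma^2) when alpha = 0 and the
class separation of the factor grows with alpha (in SD units of the
factor's noise). Taxa ("T") and pathway ("P") latent values are
exponentiated into log-normal counts, mixed with log-normal background
features and closed to relative abundances (compositional); metabolite
("M"/"S") latent values are log-intensities, exponentiated to raw
intensities so the pipeline's log-transform recovers them.

Setting alpha = 0 plants a correlated but label-independent module — the
built-in null. :func:`permute_labels` provides the complementary
empirical null in which all structure is kept but the label is shuffled.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ABUNDANCE_OMICS,
    MultiOmicDataset,
    OmicTable,
    ScaleState,
)

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "permute_labels",
    "recovery_score",
]


@dataclasses.dataclass
class ModuleSpec:
    """One planted module: per-omic feature counts and effect parameters.

    ``alpha`` shifts the module's latent factor between classes (in SD
    units of the factor noise); ``beta`` scales how strongly each planted
    feature loads on the factor; ``sigma`` is the per-feature noise SD.
    """

    features_per_omic: Mapping[str, int]
    alpha: float = 1.5
    beta: float = 1.0
    sigma: float = 0.7


@dataclasses.dataclass
class SyntheticSpec:
    """Full generator specification. Defaults are the standard benchmark
    conditions: 200 samples, three omics (100 T, 100 P, 60 M features),
    one planted (5, 5, 5) module with alpha = 1.5, beta = 1, sigma = 0.7."""

    n_samples: int = 200
    n_features: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"T": 100, "P": 100, "M": 60}
    )
    modules: Sequence[ModuleSpec] = dataclasses.field(
        default_factory=lambda: [ModuleSpec({"T": 5, "P": 5, "M": 5})]
    )
    background_sd: float = 1.0
    feature_mean_sd: float = 1.0
    dropout: float = 0.0  # fraction of T/P raw entries zeroed
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        if any(v < 1 for v in self.n_features.values()):
            raise ValueError("feature counts must be positive")
        for omic, total in self.n_features.items():
            planted = sum(m.features_per_omic.get(omic, 0) for m in self.modules)
            if planted > total:
                raise ValueError(
                    f"omic {omic!r}: {planted} planted features exceed table width {total}"
                )
        for m in self.modules:
            unknown = set(m.features_per_omic) - set(self.n_features)
            if unknown:
                raise ValueError(f"module references unknown omics {sorted(unknown)}")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


@dataclasses.dataclass
class GroundTruth:
    """Planted membership and effect sizes, keyed by module id."""

    members: dict[str, frozenset[tuple[str, str]]]
    alpha: dict[str, float]
    beta: dict[str, float]

    def member_features(self, module_id: str) -> frozenset[str]:
        return frozenset(f for _, f in self.members[module_id])


def generate_dataset(spec: SyntheticSpec, dataset_id: str = "synthetic") -> tuple[MultiOmicDataset, GroundTruth]:
    """Generate a labeled multi-omic dataset with the planted modules."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.zeros(n, dtype=int)
    labels[n // 2:] = 1  # balanced classes

    # latent factor per module
    z = {}
    for m_idx, mod in enumerate(spec.modules):
        z[m_idx] = mod.alpha * (labels - 0.5) * 2.0 + rng.standard_normal(n)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    omics: list[OmicTable] = []
    truth_members: dict[str, set[tuple[str, str]]] = {
        f"planted{m}": set() for m in range(len(spec.modules))
    }

    for omic_id, width in spec.n_features.items():
        log_vals = np.empty((n, width))
        # per-feature baseline means give realistic abundance heterogeneity
        feat_means = rng.normal(0.0, spec.feature_mean_sd, size=width)
        col = 0
        planted_cols: dict[int, list[int]] = {}
        for m_idx, mod in enumerate(spec.modules):
            k = mod.features_per_omic.get(omic_id, 0)
            for _ in range(k):
                noise = rng.standard_normal(n)
                log_vals[:, col] = feat_means[col] + mod.beta * z[m_idx] + mod.sigma * noise
                planted_cols.setdefault(m_idx, []).append(col)
                col += 1
        # background features
        while col < width:
            log_vals[:, col] = feat_means[col] + spec.background_sd * rng.standard_normal(n)
            col += 1

        names = []
        lookup = {c: m for m, cols in planted_cols.items() for c in cols}
        for c in range(width):
            if c in lookup:
                names.append(f"{omic_id}:mod{lookup[c]}_f{c:03d}")
            else:
                names.append(f"{omic_id}:bg_f{c:03d}")
        raw = np.exp(log_vals)
        if omic_id in ABUNDANCE_OMICS and spec.dropout > 0:
            mask = rng.random(raw.shape) < spec.dropout
            raw = np.where(mask, 0.0, raw)
            raw[raw.sum(axis=1) == 0, 0] = 1.0  # keep every sample's profile non-empty
        df = pd.DataFrame(raw, index=sample_ids, columns=names)
        omics.append(OmicTable(omic_id=omic_id, data=df, scale_state=ScaleState.RAW))

        for m_idx, cols in planted_cols.items():
            for c in cols:
                truth_members[f"planted{m_idx}"].add((omic_id, names[c]))

    dataset = MultiOmicDataset(
        omics=omics,
        labels=pd.Series(labels, index=sample_ids, name="label"),
        dataset_id=dataset_id,
    )
    truth = GroundTruth(
        members={k: frozenset(v) for k, v in truth_members.items()},
        alpha={f"planted{m}": mod.alpha for m, mod in enumerate(spec.modules)},
        beta={f"planted{m}": mod.beta for m, mod in enumerate(spec.modules)},
    )
    return dataset, truth


def permute_labels(dataset: MultiOmicDataset, rng: np.random.Generator) -> MultiOmicDataset:
    """Shuffle the phenotype labels uniformly; omic tables are untouched."""
    perm = rng.permutation(dataset.n_samples)
    new_labels = pd.Series(
        dataset.labels.to_numpy()[perm], index=dataset.labels.index, name=dataset.labels.name
    )
    return MultiOmicDataset(omics=dataset.omics, labels=new_labels, dataset_id=dataset.dataset_id)


def _f1(found: frozenset[str], truth: frozenset[str]) -> float:
    if not found or not truth:
        return 0.0
    tp = len(found & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(found)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


def recovery_score(
    found_modules: Sequence[Sequence[str] | frozenset[str]],
    truth: GroundTruth,
    classified: Optional[Sequence[bool]] = None,
) -> dict:
    """Best-F1 recovery of each planted module by the found modules.

    Returns per-planted-module best F1 (match over member feature sets),
    the mean across planted modules, and the number of false-positive
    modules (found modules sharing no planted feature that were
    nevertheless classified as disease-associated, when ``classified``
    flags are supplied).
    """
    found_sets = [frozenset(m) for m in found_modules]
    all_planted = frozenset(f for mems in truth.members.values() for _, f in mems)
    per_module = {}
    for mid in truth.members:
        tm = truth.member_features(mid)
        per_module[mid] = max((_f1(fs, tm) for fs in found_sets), default=0.0)
    false_pos = 0
    for i, fs in enumerate(found_sets):
        if fs and not (fs & all_planted):
            if classified is None or classified[i]:
                false_pos += 1
    return {
        "per_module_f1": per_module,
        "mean_f1": float(np.mean(list(per_module.values()))) if per_module else 0.0,
        "false_positive_modules": false_pos,
    }
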