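"""Core in-memory containers shared across the pipeline.

An :class:`OmicTable` holds one omic's samples × features matrix together
with a short omic tag ("T" taxa, "P" pathways, "M" fecal metabolites,
"S" serum metabolites) and a record of the scale the values are on.
A :class:`MultiOmicDataset` bundles several omic tables measured on the
same samples with a binary case/control label per sample.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleState",
    "OmicTable",
    "MultiOmicDataset",
    "PipelineConfig",
    "ModuleRecord",
    "ABUNDANCE_OMICS",
    "INTENSITY_OMICS",
]

#: Omic tags whose tables are compositional counts/abundances (TSS applies).
ABUNDANCE_OMICS = frozenset({"T", "P"})
#: Omic tags whose tables are intensity measurements (log-transform applies).
INTENSITY_OMICS = frozenset({"M", "S"})


class ScaleState(str, enum.Enum):
    """The transformation state of an omic table's values."""

    RAW = "raw"
    RELATIVE = "relative"
    LOG = "log"
    STANDARDIZED = "standardized"


@dataclasses.dataclass
class OmicTable:
    """One omic's samples × features matrix.

    Parameters
    ----------
    omic_id:
        Short tag identifying the omic (e.g. ``"T"``).
    data:
        DataFrame with samples in rows and features in columns. Feature
        names are expected to be namespaced as ``"<omic_id>:<name>"`` when
        produced by :func:`crossomic.io.read_feature_table`.
    scale_state:
        Which transformations have been applied, see :class:`ScaleState`.
    """

    omic_id: str
    data: pd.DataFrame
    scale_state: ScaleState = ScaleState.RAW

    def __post_init__(self) -> None:
        self.validate()

    # -- views -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.data.shape[1] == 0:
            raise ValueError(f"omic {self.omic_id!r}: table has no features")
        if self.data.shape[0] == 0:
            raise ValueError(f"omic {self.omic_id!r}: table has no samples")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"omic {self.omic_id!r}: duplicate sample ids {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"omic {self.omic_id!r}: duplicate feature ids {dups}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"omic {self.omic_id!r}: non-numeric values present")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"omic {self.omic_id!r}: missing or non-finite values")
        if self.scale_state == ScaleState.RELATIVE:
            # rows sum to 1 right after TSS; feature filtering afterwards
            # leaves a subcomposition, so sums may only fall below 1
            sums = vals.sum(axis=1)
            bad = (sums <= 0) | (sums > 1.0 + 1e-8)
            if bad.any():
                names = np.asarray(self.data.index)[bad]
                raise ValueError(
                    f"omic {self.omic_id!r}: relative rows outside (0, 1]: {names[:5].tolist()}"
                )

    def with_data(self, data: pd.DataFrame, scale_state: Optional[ScaleState] = None) -> "OmicTable":
        """Return a copy holding ``data`` (and optionally a new scale state)."""
        return OmicTable(
            omic_id=self.omic_id,
            data=data,
            scale_state=self.scale_state if scale_state is None else scale_state,
        )


@dataclasses.dataclass
class MultiOmicDataset:
    """Two or more omic tables on the same samples plus a binary phenotype.

    ``labels`` is a pandas Series indexed by sample id with values in
    {0, 1} (0 = control, 1 = case), in the same order as every omic table.
    """

    omics: list[OmicTable]
    labels: pd.Series
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.omics) < 1:
            raise ValueError("dataset needs at least one omic table")
        ref = self.omics[0].sample_ids
        for om in self.omics[1:]:
            if om.sample_ids != ref:
                raise ValueError(
                    f"omic {om.omic_id!r} sample order differs from omic "
                    f"{self.omics[0].omic_id!r}"
                )
        if list(self.labels.index) != ref:
            raise ValueError("labels are not aligned with the omic tables")
        uniq = set(self.labels.unique().tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
        counts = self.labels.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(
                "labels must contain at least 2 samples in each class; "
                f"got counts {counts.to_dict()}"
            )
        tags = [om.omic_id for om in self.omics]
        if len(set(tags)) != len(tags):
            raise ValueError(f"duplicate omic tags: {tags}")
        all_feats = [f for om in self.omics for f in om.feature_ids]
        if len(set(all_feats)) != len(all_feats):
            raise ValueError("feature ids collide across omics; prefix them with the omic tag")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.omics[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def omic_ids(self) -> list[str]:
        return [om.omic_id for om in self.omics]

    def omic(self, omic_id: str) -> OmicTable:
        for om in self.omics:
            if om.omic_id == omic_id:
                return om
        raise KeyError(f"no omic {omic_id!r} in dataset {self.dataset_id!r}")

    def feature_frame(self) -> pd.DataFrame:
        """All omics concatenated column-wise (early-integration view).

        Cached: callers must not mutate the returned frame.
        """
        cached = getattr(self, "_frame_cache", None)
        if cached is None:
            cached = pd.concat([om.data for om in self.omics], axis=1)
            object.__setattr__(self, "_frame_cache", cached)
        return cached

    def feature_omic_map(self) -> dict[str, str]:
        return {f: om.omic_id for om in self.omics for f in om.feature_ids}

    def subset_samples(self, sample_ids: Sequence[str]) -> "MultiOmicDataset":
        ids = list(sample_ids)
        return MultiOmicDataset(
            omics=[om.with_data(om.data.loc[ids]) for om in self.omics],
            labels=self.labels.loc[ids],
            dataset_id=self.dataset_id,
        )


def _as_keep_map(keep, omic_ids: Sequence[str]) -> dict[str, int]:
    if isinstance(keep, Mapping):
        missing = [o for o in omic_ids if o not in keep]
        if missing:
            raise ValueError(f"keep missing entries for omics {missing}")
        return {o: int(keep[o]) for o in omic_ids}
    return {o: int(keep) for o in omic_ids}


@dataclasses.dataclass
class PipelineConfig:
    """Parameters of the module-discovery pipeline.

    ``keep`` is the number of features retained per omic per sGCCA
    component (int applied to all omics, or a per-omic mapping). ``des``
    weights omic-omic connections in the design matrix (the label block
    is always connected to every omic with weight 1). ``nrep`` is the
    total number of subsample runs; each run uses ``(nfol-1)/nfol`` of
    the samples. ``edge`` is the co-occurrence frequency needed for a
    consensus-network edge.
    """

    keep: int | Mapping[str, int] = 10
    des: float = 1.0
    nrep: int = 100
    nfol: int = 5
    ncomp: int = 5
    edge: float = 0.8
    auc_threshold: float = 0.7
    n_null: int = 100
    min_prevalence: float = 0.15
    min_mean_abundance: float = 5e-5
    collinearity_threshold: float = 0.99
    pseudocount: Optional[float] = None  # None -> half min positive per column
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 1000
    exclusion_list: tuple[str, ...] = ()
    sparsity_mode: str = "soft"  # or "hard"
    exceedance_rule: str = "mean"  # or "p95"
    absolute_rho: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.edge <= 1):
            raise ValueError(f"edge must be in (0, 1], got {self.edge}")
        if self.nfol < 2:
            raise ValueError(f"nfol must be >= 2, got {self.nfol}")
        if self.ncomp < 1:
            raise ValueError(f"ncomp must be >= 1, got {self.ncomp}")
        if self.nrep < 1:
            raise ValueError(f"nrep must be >= 1, got {self.nrep}")
        keeps = self.keep.values() if isinstance(self.keep, Mapping) else [self.keep]
        if any(int(k) < 1 for k in keeps):
            raise ValueError(f"keep must be >= 1 per omic, got {self.keep}")
        if not (0.5 < self.auc_threshold < 1):
            raise ValueError(f"auc_threshold must be in (0.5, 1), got {self.auc_threshold}")
        if self.des < 0:
            raise ValueError(f"des must be non-negative, got {self.des}")
        if self.sparsity_mode not in ("soft", "hard"):
            raise ValueError(f"sparsity_mode must be 'soft' or 'hard', got {self.sparsity_mode}")
        if self.exceedance_rule not in ("mean", "p95"):
            raise ValueError(f"exceedance_rule must be 'mean' or 'p95', got {self.exceedance_rule}")

    def keep_map(self, omic_ids: Sequence[str]) -> dict[str, int]:
        return _as_keep_map(self.keep, omic_ids)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "exclusion_list" in d and d["exclusion_list"] is not None:
            d["exclusion_list"] = tuple(d["exclusion_list"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion_list"] = list(d["exclusion_list"])
        if isinstance(self.keep, Mapping):
            d["keep"] = dict(self.keep)
        return d


@dataclasses.dataclass
class ModuleRecord:
    """A consensus module: members, consensus-network edges, evaluation."""

    module_id: str
    members: list[tuple[str, str]]  # (omic_id, feature_id)
    edges: list[tuple[str, str, float]]  # (feature, feature, co-occurrence freq)
    evaluation: Optional["ModuleEvaluation"] = None  # noqa: F821 (set later)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"module {self.module_id!r} has fewer than 2 members")
        member_feats = {f for _, f in self.members}
        for a, b, w in self.edges:
            if a not in member_feats or b not in member_feats:
                raise ValueError(f"module {self.module_id!r}: edge ({a},{b}) endpoint not a member")
            if not (0 <= w <= 1):
                raise ValueError(f"module {self.module_id!r}: edge frequency {w} outside [0,1]")

    @property
    def feature_ids(self) -> list[str]:
        return [f for _, f in self.members]

    @property
    def omic_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for omic, _ in self.members:
            out[omic] = out.get(omic, 0) + 1
        return out

    @property
    def is_multi_omic(self) -> bool:
        return len(self.omic_counts) >= 2

    def __len__(self) -> int:
        return len(self.members)
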