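"""Evaluation of consensus modules against size-matched random nulls.

A consensus module is summarized by the first principal component (PC1)
of its centered, unit-variance member features; the module's predictive
power is the rank-based AUC of that PC1 against the phenotype
(orientation-corrected, since the PC sign is arbitrary). Cross-omic
cohesion is the mean pairwise Spearman correlation between member
features from different omics. Both statistics are benchmarked against
"null" modules that draw the same number of features from the same
omics uniformly at random. A module passing AUC > 0.7, both null
exceedances, and spanning >= 2 omics is classified disease-associated.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import ModuleRecord, MultiOmicDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NullSummary",
    "ModuleEvaluation",
    "module_pc1",
    "pc1_auc",
    "sample_null_module",
    "null_distributions",
    "cross_omic_correlation",
    "classify_module",
    "evaluate_module",
    "differential_direction",
    "modules_pc_rf",
]


@dataclasses.dataclass
class NullSummary:
    """Observed statistic vs the distribution over random null modules."""

    n_null: int
    null_mean: float
    null_sd: float
    observed: float
    exceedance: bool
    null_p95: float = float("nan")


@dataclasses.dataclass
class ModuleEvaluation:
    auc: float
    auc_null: NullSummary
    cross_omic_rho: float
    rho_null: NullSummary
    pairwise_stats: pd.DataFrame  # feature_a, feature_b, rho, q
    is_multi_omic: bool
    is_disease_associated: bool
    explained_variance: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_null_mean": self.auc_null.null_mean,
            "auc_null_sd": self.auc_null.null_sd,
            "auc_exceedance": self.auc_null.exceedance,
            "rho": self.cross_omic_rho,
            "rho_null_mean": self.rho_null.null_mean,
            "rho_null_sd": self.rho_null.null_sd,
            "rho_exceedance": self.rho_null.exceedance,
            "is_multi_omic": self.is_multi_omic,
            "is_disease_associated": self.is_disease_associated,
            "pc1_explained_variance": self.explained_variance,
        }


def _module_matrix(dataset: MultiOmicDataset, features: Sequence[str]) -> pd.DataFrame:
    frame = dataset.feature_frame()
    missing = [f for f in features if f not in frame.columns]
    if missing:
        raise KeyError(f"module features absent from dataset: {missing[:5]}")
    return frame[list(features)]


def module_pc1(
    dataset: MultiOmicDataset, features: Sequence[str], return_evr: bool = False
):
    """PC1 scores of the module's centered, unit-variance submatrix.

    Constant features cannot be scaled and are dropped with a warning.
    """
    sub = _module_matrix(dataset, features)
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        dropped = [f for f, z in zip(sub.columns, sd == 0) if z]
        logger.warning("dropping constant module feature(s): %s", dropped[:5])
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    if X.shape[1] < 1:
        raise ValueError("module has no non-constant features")
    Z = (X - X.mean(axis=0)) / sd
    # PC1 via SVD of the standardized matrix
    u, s, _vt = np.linalg.svd(Z, full_matrices=False)
    scores = u[:, 0] * s[0]
    evr = float(s[0] ** 2 / np.sum(s**2))
    if return_evr:
        return scores, evr
    return scores


def pc1_auc(scores: np.ndarray, labels: Sequence[int]) -> float:
    """Orientation-corrected rank AUC: max(A, 1 - A), PC sign is arbitrary."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required to compute an AUC")
    a = roc_auc_score(y, np.asarray(scores, dtype=float))
    return float(max(a, 1.0 - a))


def sample_null_module(
    dataset: MultiOmicDataset,
    size_per_omic: dict[str, int],
    rng: np.random.Generator,
) -> list[str]:
    """Random feature set matching the observed module's per-omic counts."""
    out: list[str] = []
    for omic_id, k in size_per_omic.items():
        feats = dataset.omic(omic_id).feature_ids
        if k > len(feats):
            raise ValueError(
                f"omic {omic_id!r} has {len(feats)} features; cannot draw {k}"
            )
        chosen = rng.choice(len(feats), size=k, replace=False)
        out.extend(feats[i] for i in sorted(chosen))
    return out


def cross_omic_correlation(
    dataset: MultiOmicDataset,
    members: Sequence[tuple[str, str]],
    absolute: bool = False,
    with_pvalues: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Mean pairwise Spearman rho between member features of different omics.

    Returns NaN (and an empty table) for single-omic modules, which are
    excluded from the multi-omic classification. ``with_pvalues=False``
    skips the per-pair table (used when scoring many null modules, where
    only the mean is needed): Spearman rho is then computed in one shot
    as the Pearson correlation of the column ranks.
    """
    omics = {o for o, _ in members}
    empty = pd.DataFrame(columns=["feature_a", "feature_b", "rho", "p", "q"])
    if len(omics) < 2:
        return float("nan"), empty
    frame = dataset.feature_frame()
    feats = [f for _, f in members]
    tags = [o for o, _ in members]
    if not with_pvalues:
        ranks = np.apply_along_axis(rankdata, 0, frame[feats].to_numpy(dtype=float))
        with np.errstate(invalid="ignore"):
            rho_mat = np.corrcoef(ranks, rowvar=False)
        vals = [
            rho_mat[i, j]
            for i in range(len(feats))
            for j in range(i + 1, len(feats))
            if tags[i] != tags[j]
        ]
        arr = np.abs(vals) if absolute else np.asarray(vals)
        return float(np.nanmean(arr)), empty
    rows = []
    for (oa, fa), (ob, fb) in combinations(members, 2):
        if oa == ob:
            continue
        res = spearmanr(frame[fa].to_numpy(), frame[fb].to_numpy())
        rows.append((fa, fb, float(res.statistic), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    rhos = table["rho"].to_numpy()
    mean_rho = float(np.mean(np.abs(rhos) if absolute else rhos))
    return mean_rho, table


def _null_stat_summary(
    observed: float, null_values: np.ndarray, rule: str = "mean"
) -> NullSummary:
    null_values = np.asarray(null_values, dtype=float)
    mean = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1)) if len(null_values) > 1 else 0.0
    p95 = float(np.quantile(null_values, 0.95))
    if rule == "mean":
        exceed = bool(observed > mean)
    elif rule == "p95":
        exceed = bool(observed > p95)
    else:
        raise ValueError(f"unknown exceedance rule {rule!r}")
    return NullSummary(
        n_null=len(null_values),
        null_mean=mean,
        null_sd=sd,
        observed=float(observed),
        exceedance=exceed,
        null_p95=p95,
    )


def null_distributions(
    dataset: MultiOmicDataset,
    module: ModuleRecord,
    n_null: int = 100,
    rng: Optional[np.random.Generator] = None,
    exceedance_rule: str = "mean",
    absolute_rho: bool = False,
    observed_auc: Optional[float] = None,
    observed_rho: Optional[float] = None,
) -> tuple[NullSummary, NullSummary]:
    """Benchmark the module's AUC and cross-omic rho against random modules.

    Each null module redraws the same per-omic feature counts uniformly,
    then is scored exactly like the observed module.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    y = dataset.labels.to_numpy()
    counts = module.omic_counts
    if observed_auc is None:
        observed_auc = pc1_auc(module_pc1(dataset, module.feature_ids), y)
    if observed_rho is None:
        observed_rho, _ = cross_omic_correlation(dataset, module.members, absolute_rho)

    null_aucs, null_rhos = [], []
    for _ in range(n_null):
        feats = sample_null_module(dataset, counts, rng)
        null_aucs.append(pc1_auc(module_pc1(dataset, feats), y))
        members = [(f.split(":", 1)[0], f) for f in feats]
        rho, _ = cross_omic_correlation(dataset, members, absolute_rho, with_pvalues=False)
        null_rhos.append(rho)
    auc_summary = _null_stat_summary(observed_auc, np.array(null_aucs), exceedance_rule)
    rho_arr = np.array(null_rhos, dtype=float)
    if np.isnan(observed_rho) or np.isnan(rho_arr).all():
        rho_summary = NullSummary(
            n_null=n_null, null_mean=float("nan"), null_sd=float("nan"),
            observed=float(observed_rho), exceedance=False,
        )
    else:
        rho_summary = _null_stat_summary(observed_rho, rho_arr[~np.isnan(rho_arr)], exceedance_rule)
    return auc_summary, rho_summary


def classify_module(evaluation: ModuleEvaluation, auc_threshold: float = 0.7) -> bool:
    """Disease-associated = multi-omic AND AUC > threshold AND both exceedances."""
    return bool(
        evaluation.is_multi_omic
        and evaluation.auc > auc_threshold
        and evaluation.auc_null.exceedance
        and evaluation.rho_null.exceedance
    )


def evaluate_module(
    dataset: MultiOmicDataset,
    module: ModuleRecord,
    n_null: int = 100,
    rng: Optional[np.random.Generator] = None,
    auc_threshold: float = 0.7,
    exceedance_rule: str = "mean",
    absolute_rho: bool = False,
) -> ModuleEvaluation:
    """Full evaluation of one consensus module (AUC, rho, nulls, class)."""
    y = dataset.labels.to_numpy()
    scores, evr = module_pc1(dataset, module.feature_ids, return_evr=True)
    auc = pc1_auc(scores, y)
    rho, pairwise = cross_omic_correlation(dataset, module.members, absolute_rho)
    auc_null, rho_null = null_distributions(
        dataset,
        module,
        n_null=n_null,
        rng=rng,
        exceedance_rule=exceedance_rule,
        absolute_rho=absolute_rho,
        observed_auc=auc,
        observed_rho=rho,
    )
    evaluation = ModuleEvaluation(
        auc=auc,
        auc_null=auc_null,
        cross_omic_rho=rho,
        rho_null=rho_null,
        pairwise_stats=pairwise,
        is_multi_omic=module.is_multi_omic,
        is_disease_associated=False,
        explained_variance=evr,
    )
    evaluation.is_disease_associated = classify_module(evaluation, auc_threshold)
    return evaluation


def differential_direction(
    dataset: MultiOmicDataset,
    module: ModuleRecord,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney direction (up/down/ns) with BH-FDR per omic."""
    frame = dataset.feature_frame()
    y = dataset.labels.to_numpy()
    rows = []
    for omic_id, feat in module.members:
        x = frame[feat].to_numpy(dtype=float)
        case, ctrl = x[y == 1], x[y == 0]
        stat, p = mannwhitneyu(case, ctrl, alternative="two-sided")
        diff = float(np.median(case) - np.median(ctrl))
        rows.append({"feature": feat, "omic": omic_id, "U": float(stat), "p": float(p), "median_diff": diff})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for omic_id in table["omic"].unique():
        mask = table["omic"] == omic_id
        table.loc[mask, "q"] = multipletests(table.loc[mask, "p"].to_numpy(), method="fdr_bh")[1]
    table["direction"] = "ns"
    sig = table["q"] < fdr
    table.loc[sig & (table["median_diff"] > 0), "direction"] = "up"
    table.loc[sig & (table["median_diff"] < 0), "direction"] = "down"
    return table


def modules_pc_rf(
    dataset: MultiOmicDataset,
    modules: Sequence[ModuleRecord],
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    n_estimators: int = 500,
) -> dict:
    """Cross-validated AUC of a random forest on the modules' PC1 scores.

    PCA loadings (and the feature scaling) are fitted on training folds
    only and applied to held-out samples, so the reported AUC is an
    honest out-of-sample estimate.
    """
    if not modules:
        raise ValueError("at least one module is required")
    frame = dataset.feature_frame()
    y = dataset.labels.to_numpy()
    rng = np.random.SeedSequence(seed)
    fold_seeds = rng.generate_state(repeats)
    aucs = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[r] % (2**31 - 1)))
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            train_scores, test_scores = [], []
            for module in modules:
                X = frame[module.feature_ids].to_numpy(dtype=float)
                Xtr, Xte = X[train_idx], X[test_idx]
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=1)
                ok = sd > 0
                if not ok.any():
                    train_scores.append(np.zeros(len(train_idx)))
                    test_scores.append(np.zeros(len(test_idx)))
                    continue
                Ztr = (Xtr[:, ok] - mu[ok]) / sd[ok]
                Zte = (Xte[:, ok] - mu[ok]) / sd[ok]
                _u, _s, vt = np.linalg.svd(Ztr, full_matrices=False)
                pc = vt[0]
                train_scores.append(Ztr @ pc)
                test_scores.append(Zte @ pc)
            Ftr = np.column_stack(train_scores)
            Fte = np.column_stack(test_scores)
            if len(np.unique(y[test_idx])) < 2:
                logger.warning("test fold with a single class skipped")
                continue
            clf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=int(fold_seeds[r] % (2**31 - 1))
            )
            clf.fit(Ftr, y[train_idx])
            prob = clf.predict_proba(Fte)[:, 1]
            aucs.append(roc_auc_score(y[test_idx], prob))
    return {
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        "fold_aucs": [float(a) for a in aucs],
        "n_modules": len(modules),
        "n_features_total": int(sum(len(m) for m in modules)),
    }
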