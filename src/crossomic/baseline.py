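"""Early-integration random-forest baseline with feature selection.

All omic tables are concatenated ("early integration") and disease
predictability is estimated by repeated stratified cross-validation
(default 5 folds x 10 repeats = 50 fold-models). Inside each training
fold an all-relevant shadow-feature selection is run (each real
feature's importance is compared against permuted "shadow" copies over
several forest fits, with binomial accept/reject decisions), a random
forest is trained on the selected features, and held-out AUC is scored.

Feature importance uses the forest's permutation importance averaged over
folds; per-feature significance comes from a label-permutation scheme
(importance under refits on permuted labels), p = (1 + #null >= obs) /
(n_perms + 1), BH-FDR corrected. "Contributors" are features selected in
>= 50% of fold-models with importance FDR < 0.1.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .containers import ModuleRecord, MultiOmicDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CvResult",
    "boruta_select",
    "early_integration_cv",
    "feature_importance",
    "contributor_overlap",
]


@dataclasses.dataclass
class CvResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    mean_n_selected: float
    selection_freq: pd.Series  # per feature, fraction of fold-models
    importance_mean: Optional[pd.Series] = None  # per feature, mean over fold-models
    importance: Optional[pd.DataFrame] = None  # feature, importance, p, q, contributor

    def contributors(self) -> list[str]:
        if self.importance is None:
            raise ValueError("run feature_importance first")
        return self.importance.loc[self.importance["contributor"], "feature"].tolist()

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_n_selected": self.mean_n_selected,
            "n_folds": len(self.fold_aucs),
        }


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 10,
    alpha: float = 0.05,
    n_estimators: int = 100,
) -> np.ndarray:
    """All-relevant selection by shadow-feature permutation testing.

    Each round appends a column-permuted copy of every feature ("shadow"),
    fits a forest, and scores a hit for each real feature whose Gini
    importance exceeds the best shadow importance. After ``n_iter``
    rounds a feature is confirmed when its hit count is in the upper tail
    of Binomial(n_iter, 0.5) at level ``alpha`` (two-sided decisions:
    lower-tail features are rejected, the middle stays tentative and is
    not selected). Returns a boolean mask; if nothing is confirmed, all
    features are kept so downstream models never see an empty matrix.
    """
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = X[rng.permutation(n), j]
        Xa = np.hstack([X, shadow])
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(Xa, y)
        imp = clf.feature_importances_
        max_shadow = imp[p:].max()
        hits += imp[:p] > max_shadow
    # upper-tail binomial confirmation
    threshold = int(binom.ppf(1 - alpha, n_iter, 0.5))
    confirmed = hits > threshold
    if not confirmed.any():
        logger.warning("shadow selection confirmed no features; keeping all %d", p)
        return np.ones(p, dtype=bool)
    return confirmed


def early_integration_cv(
    dataset: MultiOmicDataset,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    selection_iters: int = 10,
    selection_estimators: int = 100,
) -> CvResult:
    """Repeated CV of the early-integration random forest.

    Selection and training happen strictly inside each training fold;
    held-out samples only ever contribute to the fold's AUC.
    """
    frame = dataset.feature_frame()
    feature_ids = list(frame.columns)
    X = frame.to_numpy(dtype=float)
    y = dataset.labels.to_numpy()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(repeats * 2)

    fold_aucs: list[float] = []
    n_selected: list[int] = []
    sel_counts = np.zeros(X.shape[1], dtype=int)
    imp_sums = np.zeros(X.shape[1])
    n_fold_models = 0
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rep_seeds[r] % (2**31 - 1))
        )
        rng = np.random.default_rng(rep_seeds[repeats + r])
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
                logger.warning("fold with a single class skipped")
                continue
            mask = boruta_select(
                X[train_idx], y[train_idx], rng,
                n_iter=selection_iters, n_estimators=selection_estimators,
            )
            n_fold_models += 1
            sel_counts += mask
            n_selected.append(int(mask.sum()))
            clf = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            cols = np.flatnonzero(mask)
            clf.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            prob = clf.predict_proba(X[np.ix_(test_idx, cols)])[:, 1]
            fold_aucs.append(float(roc_auc_score(y[test_idx], prob)))
            # out-of-fold permutation importance of this fold-model;
            # unselected features count 0 for the fold
            imp = permutation_importance(
                clf, X[np.ix_(test_idx, cols)], y[test_idx],
                n_repeats=5, random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            ).importances_mean
            imp_sums[cols] += imp
    if not fold_aucs:
        raise RuntimeError("no usable folds")
    freq = pd.Series(sel_counts / n_fold_models, index=feature_ids, name="selection_freq")
    imp_mean = pd.Series(imp_sums / n_fold_models, index=feature_ids, name="importance")
    return CvResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        mean_n_selected=float(np.mean(n_selected)),
        selection_freq=freq,
        importance_mean=imp_mean,
    )


def feature_importance(
    dataset: MultiOmicDataset,
    cv_result: CvResult,
    n_label_perms: int = 100,
    seed: int = 0,
    min_selection_freq: float = 0.5,
    fdr_threshold: float = 0.1,
    n_estimators: int = 100,
) -> CvResult:
    """Label-permutation p-values for the fold-model importances.

    The observed importance of each feature is its mean out-of-fold
    permutation importance over the cross-validation fold-models (from
    ``early_integration_cv``). The null refits a forest on permuted labels
    ``n_label_perms`` times and scores importance the same way;
    p = (1 + #null >= obs) / (n_label_perms + 1) with BH-FDR across
    features. Features selected in >= ``min_selection_freq`` of
    fold-models with q < ``fdr_threshold`` are flagged contributors.
    """
    if cv_result.importance_mean is None:
        raise ValueError("cv_result lacks fold importances; rerun early_integration_cv")
    frame = dataset.feature_frame()
    X = frame.to_numpy(dtype=float)
    y = dataset.labels.to_numpy()
    feature_ids = list(frame.columns)
    rng = np.random.default_rng(seed)
    obs = cv_result.importance_mean.reindex(feature_ids).fillna(0.0).to_numpy()

    exceed = np.zeros(len(feature_ids), dtype=int)
    for _ in range(n_label_perms):
        y_perm = y[rng.permutation(len(y))]
        clf_p = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        )
        clf_p.fit(X, y_perm)
        null_imp = permutation_importance(
            clf_p, X, y_perm, n_repeats=1, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        ).importances_mean
        exceed += null_imp >= obs
    p = (1 + exceed) / (n_label_perms + 1)
    q = multipletests(p, method="fdr_bh")[1]
    freq = cv_result.selection_freq.reindex(feature_ids).fillna(0.0).to_numpy()
    table = pd.DataFrame(
        {
            "feature": feature_ids,
            "omic": [f.split(":", 1)[0] for f in feature_ids],
            "selection_freq": freq,
            "importance": obs,
            "p": p,
            "q": q,
        }
    )
    table["contributor"] = (table["selection_freq"] >= min_selection_freq) & (
        table["q"] < fdr_threshold
    )
    return dataclasses.replace(cv_result, importance=table)


def contributor_overlap(
    modules: Sequence[ModuleRecord],
    cv_result: CvResult,
) -> dict:
    """Fraction of each module's features that are baseline contributors."""
    contributors = set(cv_result.contributors())
    per_module = {}
    for m in modules:
        feats = set(m.feature_ids)
        per_module[m.module_id] = len(feats & contributors) / len(feats)
    vals = list(per_module.values())
    return {
        "per_module": per_module,
        "mean": float(np.mean(vals)) if vals else float("nan"),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
    }
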