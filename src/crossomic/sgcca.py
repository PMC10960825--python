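"""Sparse generalized canonical correlation analysis (sGCCA).

Multi-block CCA in which each omic block X_j receives a sparse loading
vector a_j so that the latent variates t_j = X_j a_j maximally co-vary
according to a block design matrix C:

    maximize  sum_{j<k} c_jk * cov(X_j a_j, X_k a_k)
    s.t.      ||a_j||_2 = 1,  a_j has at most keep_j non-zero entries.

The binary phenotype enters as an extra single-feature block ("label
block") connected to every omic block, steering the variates toward
directions that also separate cases from controls. Successive components
are obtained by regression deflation of the omic blocks; the label block
is never deflated.

The solver is a block-coordinate ascent: each inner update sets
u_j = X_j^T (sum_k c_jk t_k), soft-thresholds u_j so exactly keep_j
entries survive, and renormalizes. Each component starts from each
block's dominant right singular vector and first runs the ascent with no
sparsity constraint (a dense warm start that aligns the blocks with the
globally dominant covariance direction) before the sparse ascent; this
initialization is deterministic, so all run-to-run variation comes from
the data subsampling upstream, and it avoids the local optima a direct
sparse ascent falls into on small blocks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "SgccaComponent",
    "SgccaModel",
    "PutativeModule",
    "encode_label_block",
    "make_design",
    "fit_sgcca",
    "extract_putative_modules",
]

LABEL_BLOCK = "__label__"


@dataclasses.dataclass
class DesignMatrix:
    """Symmetric non-negative block-connectivity matrix with zero diagonal."""

    C: np.ndarray
    block_names: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("design matrix must be square")
        if C.shape[0] != len(self.block_names):
            raise ValueError("design matrix size must match number of blocks")
        if not np.allclose(C, C.T):
            raise ValueError("design matrix must be symmetric")
        if (C < 0).any():
            raise ValueError("design matrix entries must be non-negative")
        if not np.allclose(np.diag(C), 0):
            raise ValueError("design matrix diagonal must be zero")
        self.C = C


@dataclasses.dataclass
class SgccaComponent:
    """One component: per-block sparse loadings and latent variates."""

    loadings: list[np.ndarray]  # a_j per block, unit 2-norm
    variates: list[np.ndarray]  # t_j = X_j a_j per block
    n_iter: int
    criterion: float
    converged: bool


@dataclasses.dataclass
class SgccaModel:
    components: list[SgccaComponent]
    design: DesignMatrix
    keep: list[int]  # per omic block
    block_feature_ids: list[list[str]]  # per omic block
    block_names: list[str]  # omic block names (label excluded)


@dataclasses.dataclass
class PutativeModule:
    """Non-zero-loading features of one component across omic blocks."""

    component: int
    members: frozenset[tuple[str, str]]  # (omic_id, feature_id)


def encode_label_block(labels: np.ndarray) -> np.ndarray:
    """Binary labels -> one centered, unit-SD column (n x 1).

    Cases map to the positive side, controls to the negative side. The
    sign is immaterial downstream (loadings flip with it).
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("label block is constant: both classes are required")
    col = y - y.mean()
    col = col / col.std(ddof=1)
    return col.reshape(-1, 1)


def make_design(n_omics: int, des: float = 1.0, with_label: bool = True) -> DesignMatrix:
    """Design with weight ``des`` between omic pairs and 1 omic-to-label."""
    if n_omics < 1:
        raise ValueError("need at least one omic block")
    if des < 0:
        raise ValueError("des must be non-negative")
    J = n_omics + (1 if with_label else 0)
    C = np.full((J, J), float(des))
    names = [f"block{j}" for j in range(n_omics)]
    if with_label:
        C[-1, :] = 1.0
        C[:, -1] = 1.0
        names.append(LABEL_BLOCK)
    np.fill_diagonal(C, 0.0)
    return DesignMatrix(C, names)


def _sparsify(u: np.ndarray, keep: int, mode: str = "soft") -> np.ndarray:
    """Keep exactly ``min(keep, len(u))`` non-zeros of ``u``.

    Soft mode shrinks surviving magnitudes by the (keep+1)-th largest
    |u|; hard mode truncates without shrinkage. Boundary ties are broken
    toward the lowest feature index; a tied survivor keeps a tiny
    positive magnitude so the exact non-zero count holds.
    """
    p = len(u)
    k = min(keep, p)
    if k >= p:
        return u.copy()
    absu = np.abs(u)
    # partition puts the k largest magnitudes at the tail
    part = np.argpartition(absu, p - k)
    kept = part[p - k :]
    lam = absu[part[p - k - 1]]
    if absu[kept].min() == lam:
        # boundary tie: fall back to a stable order keeping lowest indices
        order = np.lexsort((np.arange(p), -absu))
        kept = order[:k]
        lam = absu[order[k]]
    out = np.zeros_like(u)
    if mode == "soft":
        mags = absu[kept] - lam
        tiny = np.finfo(float).tiny
        mags = np.where(mags <= 0, tiny, mags)
        out[kept] = np.sign(u[kept]) * mags
    elif mode == "hard":
        out[kept] = u[kept]
    else:
        raise ValueError(f"unknown sparsity mode {mode!r}")
    return out


def _criterion(C: np.ndarray, variates: list[np.ndarray]) -> float:
    """Design-weighted sum of covariances between block variates."""
    n = len(variates[0])
    val = 0.0
    for j in range(len(variates)):
        for k in range(j + 1, len(variates)):
            if C[j, k] != 0:
                val += C[j, k] * float(variates[j] @ variates[k]) / (n - 1)
    return val


def _init_loading(X: np.ndarray) -> np.ndarray:
    """Dominant right singular vector, sign-fixed for determinism."""
    if X.shape[1] == 1:
        return np.ones(1)
    # economical: eigvector of X^T X via svd of X
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    # fix sign: largest-|entry| coordinate positive
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v


def _fit_component(
    work: list[np.ndarray],
    ylab: Optional[np.ndarray],
    C: np.ndarray,
    eff_keep: list[int],
    tol: float,
    max_iter: int,
    sparsity_mode: str,
    label_sign: float,
    a_init: Optional[list[np.ndarray]] = None,
):
    """One component's block-coordinate ascent from a given label start.

    Runs a dense warm start (no sparsity) to convergence first, then the
    sparse ascent. Returns (a, t, (a_lab, t_lab) | None, (n_iter,
    converged), criterion).
    """
    J = len(work)
    n = work[0].shape[0]
    has_label = ylab is not None
    if a_init is None:
        a_init = [_init_loading(work[j]) for j in range(J)]
    a = [aj.copy() for aj in a_init]
    t = [work[j] @ a[j] for j in range(J)]
    if has_label:
        a_lab = np.array([label_sign])
        t_lab = (ylab @ a_lab).ravel()
    converged = False
    it = 0
    needs_sparsity = any(eff_keep[j] < work[j].shape[1] for j in range(J))
    phases = [None, eff_keep] if needs_sparsity else [eff_keep]
    for phase_keep in phases:
        # the dense warm start only selects a basin; a looser tolerance
        # there saves iterations without affecting the sparse solution
        phase_tol = max(tol, 1e-4) if (phase_keep is None) else tol
        converged = False
        for it in range(1, max_iter + 1):
            a_prev = [aj.copy() for aj in a]
            for j in range(J):
                omega = np.zeros(n)
                for k in range(J):
                    if k != j and C[j, k] != 0:
                        omega += C[j, k] * t[k]
                if has_label and C[j, J] != 0:
                    omega += C[j, J] * t_lab
                u = work[j].T @ omega
                if phase_keep is not None:
                    u = _sparsify(u, phase_keep[j], sparsity_mode)
                norm = np.linalg.norm(u)
                if norm <= 0:
                    # no covariance signal left in this block: keep previous direction
                    continue
                a[j] = u / norm
                t[j] = work[j] @ a[j]
            if has_label:
                # label loading is +-1; pick the sign maximizing the criterion
                omega = np.zeros(n)
                for k in range(J):
                    if C[J, k] != 0:
                        omega += C[J, k] * t[k]
                s = float(ylab.ravel() @ omega)
                a_lab = np.array([1.0 if s >= 0 else -1.0])
                t_lab = (ylab @ a_lab).ravel()
            delta = max(np.max(np.abs(a[j] - a_prev[j])) for j in range(J))
            if delta < phase_tol:
                converged = True
                break
    all_t = t + ([t_lab] if has_label else [])
    crit = _criterion(C, all_t)
    lab_pair = (a_lab, t_lab) if has_label else None
    return a, t, lab_pair, (it, converged), crit


def fit_sgcca(
    blocks: Sequence[np.ndarray],
    design: DesignMatrix,
    keep: Sequence[int],
    ncomp: int = 1,
    tol: float = 1e-6,
    max_iter: int = 1000,
    label_block: Optional[np.ndarray] = None,
    block_feature_ids: Optional[Sequence[Sequence[str]]] = None,
    block_names: Optional[Sequence[str]] = None,
    sparsity_mode: str = "soft",
) -> SgccaModel:
    """Fit ``ncomp`` sparse components over the given standardized blocks.

    ``blocks`` are the omic matrices (samples x features, standardized on
    the fitting samples). ``label_block`` is the optional encoded
    phenotype column; its keep is fixed at 1 and it is never deflated.
    ``design`` must cover omic blocks plus the label block when present
    (label last).
    """
    Xs = [np.asarray(X, dtype=float) for X in blocks]
    J = len(Xs)
    n = Xs[0].shape[0]
    if n < 3:
        raise ValueError("sGCCA needs at least 3 samples")
    if any(X.shape[0] != n for X in Xs):
        raise ValueError("all blocks must share the sample dimension")
    has_label = label_block is not None
    n_blocks = J + (1 if has_label else 0)
    if design.C.shape[0] != n_blocks:
        raise ValueError(
            f"design covers {design.C.shape[0]} blocks but {n_blocks} were supplied"
        )
    keep = [int(k) for k in keep]
    if len(keep) != J:
        raise ValueError("keep must list one count per omic block")
    eff_keep = []
    for j, k in enumerate(keep):
        if k > Xs[j].shape[1]:
            warnings.warn(
                f"keep={k} exceeds block {j} width {Xs[j].shape[1]}; clamped",
                stacklevel=2,
            )
            k = Xs[j].shape[1]
        eff_keep.append(k)

    if block_names is None:
        block_names = [f"block{j}" for j in range(J)]
    if block_feature_ids is None:
        block_feature_ids = [
            [f"{block_names[j]}:f{i}" for i in range(Xs[j].shape[1])] for j in range(J)
        ]

    work = [X.copy() for X in Xs]
    if has_label:
        ylab = np.asarray(label_block, dtype=float).reshape(n, 1)
        # canonicalize the column sign so swapping the case/control coding
        # (which only flips the encoded column) changes nothing downstream
        if ylab[0, 0] < 0:
            ylab = -ylab
    else:
        ylab = None
    components: list[SgccaComponent] = []
    C = design.C

    for h in range(ncomp):
        # the ascent is a local method: with a label block, start it from
        # both label orientations and keep the higher-criterion solution
        # (deterministic, and symmetric in the class coding by construction)
        starts = (1.0, -1.0) if has_label else (1.0,)
        a_init = [_init_loading(work[j]) for j in range(J)]
        best = None
        for label_sign in starts:
            cand = _fit_component(
                work, ylab, C, eff_keep, tol, max_iter, sparsity_mode, label_sign,
                a_init=a_init,
            )
            if best is None or cand[4] > best[4] + 1e-12:
                best = cand
        a, t, lab_pair, it_conv, crit = best
        converged = it_conv[1]
        it = it_conv[0]
        if not converged:
            warnings.warn(
                f"sGCCA component {h + 1} did not converge in {max_iter} iterations",
                stacklevel=2,
            )
        if has_label:
            a_lab, t_lab = lab_pair
            all_t = t + [t_lab]
            loadings = [aj.copy() for aj in a] + [a_lab.copy()]
        else:
            all_t = t
            loadings = [aj.copy() for aj in a]
        components.append(
            SgccaComponent(
                loadings=loadings,
                variates=[tj.copy() for tj in all_t],
                n_iter=it,
                criterion=crit,
                converged=converged,
            )
        )
        # regression deflation of each omic block on its own variate
        if h < ncomp - 1:
            for j in range(J):
                tj = t[j]
                denom = float(tj @ tj)
                if denom > 0:
                    work[j] = work[j] - np.outer(tj, (tj @ work[j]) / denom)

    return SgccaModel(
        components=components,
        design=design,
        keep=eff_keep,
        block_feature_ids=[list(f) for f in block_feature_ids],
        block_names=list(block_names),
    )


def extract_putative_modules(model: SgccaModel) -> list[PutativeModule]:
    """One putative module per component: its non-zero-loading omic features."""
    modules = []
    for h, comp in enumerate(model.components):
        members = set()
        for j, name in enumerate(model.block_names):
            a = comp.loadings[j]
            for i in np.flatnonzero(a):
                members.add((name, model.block_feature_ids[j][i]))
        modules.append(PutativeModule(component=h, members=frozenset(members)))
    return modules
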