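"""SMKL-FS: two-stage feature selection by the multiple-kernel SVM objective.

Stage 1 scores every feature individually by J, the saddle-point value
min_d max_a W(a, d) of the multiple-kernel SVM dual computed on that single
feature; smaller J means the two classes separate more easily, so the J list
is sorted ascending and the top n* features form the relevant set.

Stage 2 grows a compact subset Z by sequential forward selection: starting
from Z = {} with J_0 = +inf, each round evaluates J_{Z + {f}} for every
remaining candidate f and appends the one with the largest reduction
Delta J = J_prev - J_{Z + {f}}, stopping when Delta J <= 0, the subset
reaches r_max, or the candidates run out. The objective replaces the
classification error a wrapper would use, so no inner cross-validation is
needed during the search.

Ties everywhere break by stage-1 rank, then input order — runs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import ExpressionDataset, RunConfig
from .kernels import (
    GramMatrix,
    GramStack,
    KernelSpec,
    build_stack,
    default_kernel_bank,
    normalize_gram,
    zscore_apply,
    zscore_fit,
)
from .mkl import MKLModel, SolverSettings, solve_simplemkl

__all__ = [
    "FeatureScoreList",
    "RelevantSet",
    "ForwardTrace",
    "score_features",
    "select_relevant",
    "subset_objective",
    "forward_select",
    "smkl_fs",
]


@dataclass
class FeatureScoreList:
    """Per-feature J scores, ascending (most relevant first)."""

    entries: list  # (feature_id, J) pairs

    def feature_ids(self) -> list:
        return [f for f, _ in self.entries]

    def as_dict(self) -> dict:
        return dict(self.entries)


@dataclass
class RelevantSet:
    features: list
    n_star: int


@dataclass
class ForwardTrace:
    """Accepted subset with the objective path that produced it."""

    Z: list
    J_seq: list
    deltaJ_seq: list
    stop_reason: str  # delta_nonpositive | max_size | candidates_exhausted

    def __post_init__(self) -> None:
        if not (len(self.Z) == len(self.J_seq) == len(self.deltaJ_seq)):
            raise ValueError("trace sequences must have equal length")


def _bank_from_config(cfg: RunConfig) -> list:
    if not cfg.kernel_bank:
        return default_kernel_bank()
    return [KernelSpec(**entry) for entry in cfg.kernel_bank]


def _settings_from_config(cfg: RunConfig) -> SolverSettings:
    return SolverSettings(
        C=cfg.C,
        dual_gap_tol=cfg.dual_gap_tol,
        max_outer_iter=cfg.max_outer_iter,
        qp_tol=cfg.qp_tol,
        seed=cfg.seed,
    )


class _GramAccumulators:
    """Per-feature inner-product and squared-distance caches.

    Both the linear/polynomial kernels (functions of the inner-product Gram)
    and the RBF kernel (a function of pairwise squared distances) decompose
    additively over features, so the Gram of Z + {f} is the Gram accumulator
    of Z plus the cached contribution of f — exact, no approximation.
    """

    def __init__(self, X: np.ndarray, bank: Sequence[KernelSpec], normalize: bool = True):
        self.X = X  # samples x features, already standardized if requested
        self.bank = list(bank)
        self.normalize = normalize
        self._inner: dict = {}
        self._sq: dict = {}

    def feature_inner(self, j: int) -> np.ndarray:
        if j not in self._inner:
            col = self.X[:, j]
            self._inner[j] = np.outer(col, col)
        return self._inner[j]

    def feature_sq(self, j: int) -> np.ndarray:
        if j not in self._sq:
            col = self.X[:, j]
            self._sq[j] = (col[:, None] - col[None, :]) ** 2
        return self._sq[j]

    def stack(self, inner: np.ndarray, sq: np.ndarray, feature_subset: tuple) -> GramStack:
        mats = []
        for spec in self.bank:
            if spec.family == "linear":
                vals = inner
            elif spec.family == "rbf":
                vals = np.exp(-sq / (2.0 * spec.rbf_bandwidth))
            else:
                vals = (inner + spec.poly_offset) ** spec.poly_degree
            g = GramMatrix(values=0.5 * (vals + vals.T), spec=spec, feature_subset=feature_subset)
            if self.normalize:
                g = normalize_gram(g)
            mats.append(g)
        return GramStack(mats=mats)


def _standardized(ds: ExpressionDataset, zscore: bool) -> np.ndarray:
    X = ds.samples_by_features()
    if not np.all(np.isfinite(X)):
        raise ValueError("dataset contains missing or non-finite values; preprocess first")
    if zscore:
        X = zscore_apply(X, zscore_fit(X))
    return X


def score_features(
    ds: ExpressionDataset,
    bank: Optional[Sequence[KernelSpec]] = None,
    s: SolverSettings = SolverSettings(),
    zscore: bool = True,
    normalize: bool = True,
) -> FeatureScoreList:
    """Stage 1: J of the single-feature multiple-kernel problem, per feature.

    Zero-variance features are assigned J = +inf (ranked last) rather than
    raising — filtered expression matrices routinely contain them.
    """
    bank = list(bank) if bank is not None else default_kernel_bank()
    X = _standardized(ds, zscore)
    ranges = np.ptp(ds.X, axis=1)  # exact-zero range catches constants std misses
    scored = []
    for j, fid in enumerate(ds.feature_ids):
        if ranges[j] == 0:
            scored.append((fid, math.inf))
            continue
        stack = build_stack(X[:, [j]], bank, feature_ids=(fid,), normalize=normalize)
        model = solve_simplemkl(stack, ds.y, s)
        scored.append((fid, model.J))
    order = sorted(range(len(scored)), key=lambda i: (scored[i][1], i))
    return FeatureScoreList(entries=[scored[i] for i in order])


def select_relevant(scores: FeatureScoreList, n_star: int) -> RelevantSet:
    """Top n* entries of the ascending J list."""
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    return RelevantSet(features=scores.feature_ids()[:n_star], n_star=n_star)


def subset_objective(
    ds: ExpressionDataset,
    Z: Sequence[str],
    bank: Optional[Sequence[KernelSpec]] = None,
    s: SolverSettings = SolverSettings(),
    zscore: bool = True,
    normalize: bool = True,
) -> float:
    """J_Z: the saddle-point objective with every base kernel restricted to Z."""
    Z = list(Z)
    if not Z:
        raise ValueError("feature subset Z must be nonempty")
    bank = list(bank) if bank is not None else default_kernel_bank()
    X = _standardized(ds, zscore)
    idx = ds.feature_index(Z)
    stack = build_stack(X[:, idx], bank, feature_ids=tuple(sorted(Z)), normalize=normalize)
    return solve_simplemkl(stack, ds.y, s).J


def forward_select(
    ds: ExpressionDataset,
    candidates: RelevantSet,
    bank: Optional[Sequence[KernelSpec]] = None,
    s: SolverSettings = SolverSettings(),
    r_max: int = 10,
    zscore: bool = True,
    normalize: bool = True,
) -> ForwardTrace:
    """Stage 2: greedy growth of Z by the largest objective reduction.

    Standard sequential forward selection: every remaining candidate is
    re-evaluated each round, accepted features are never removed, and the
    candidate order (the stage-1 rank) breaks ties.
    """
    if not candidates.features:
        raise ValueError("candidate set is empty")
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    bank = list(bank) if bank is not None else default_kernel_bank()
    X = _standardized(ds, zscore)
    acc = _GramAccumulators(X, bank, normalize=normalize)
    col_of = {f: i for i, f in enumerate(ds.feature_ids)}

    remaining = list(candidates.features)
    n = ds.n_samples
    run_inner = np.zeros((n, n))
    run_sq = np.zeros((n, n))
    Z: list = []
    J_seq: list = []
    delta_seq: list = []
    J_prev = math.inf
    stop = "candidates_exhausted"

    while remaining:
        best_J = math.inf
        best_i = None
        for i, f in enumerate(remaining):
            j = col_of[f]
            inner = run_inner + acc.feature_inner(j)
            sq = run_sq + acc.feature_sq(j)
            try:
                stack = acc.stack(inner, sq, feature_subset=tuple(sorted(Z + [f])))
            except ValueError:  # degenerate subset (e.g. all-constant): not selectable
                continue
            J_new = solve_simplemkl(stack, ds.y, s).J
            if J_new < best_J:  # strict: ties keep the earlier (better-ranked) candidate
                best_J = J_new
                best_i = i
        if best_i is None or not best_J < J_prev:
            stop = "delta_nonpositive"
            break
        f = remaining.pop(best_i)
        j = col_of[f]
        run_inner += acc.feature_inner(j)
        run_sq += acc.feature_sq(j)
        Z.append(f)
        J_seq.append(best_J)
        delta_seq.append(J_prev - best_J)
        J_prev = best_J
        if len(Z) >= r_max:
            stop = "max_size"
            break
    return ForwardTrace(Z=Z, J_seq=J_seq, deltaJ_seq=delta_seq, stop_reason=stop)


def smkl_fs(ds: ExpressionDataset, cfg: RunConfig = RunConfig()) -> tuple:
    """The full two-stage method under one run configuration.

    Returns ``(FeatureScoreList, ForwardTrace)``. With ``cfg.skip_stage1``
    stage 2 runs over all features in input-matrix order (the documented
    tie-break for that mode) and the returned score list is empty.
    """
    bank = _bank_from_config(cfg)
    s = _settings_from_config(cfg)
    if cfg.skip_stage1:
        scores = FeatureScoreList(entries=[])
        candidates = RelevantSet(features=list(ds.feature_ids), n_star=len(ds.feature_ids))
    else:
        scores = score_features(ds, bank, s, zscore=cfg.zscore, normalize=cfg.trace_normalize)
        candidates = select_relevant(scores, min(cfg.n_star, ds.n_features))
    trace = forward_select(
        ds, candidates, bank, s, r_max=cfg.r_max, zscore=cfg.zscore, normalize=cfg.trace_normalize
    )
    return scores, trace
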