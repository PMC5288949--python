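"""Feature-space performance measurements and the resampling harness.

Four measurements compare feature-selection outputs:

* **effectiveness** — mean and maximum cross-validated accuracy of an SVM
  over a nested chain S_1 c S_2 c ... c S_n of top-k feature sets;
* **union stability** — |intersection| / |union| over the k sets selected on
  k subsamples of the same data;
* **independent stability** — the mean pairwise Jaccard similarity of those
  k sets;
* **similarity** — the mean intersection *size* (not Jaccard) between one
  method's selected set and the sets other methods select on the same data.

The resampling plan draws k subsamples of a fixed fraction of the samples
without replacement; paired tumor/normal samples are drawn (and folded) as
pairs so no subject straddles a train/test split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import ExpressionDataset
from .kernels import KernelSpec, build_cross_stack, build_stack, default_kernel_bank, zscore_apply, zscore_fit
from .mkl import SolverSettings, predict, solve_simplemkl

__all__ = [
    "ConfusionCounts",
    "NestedSubsets",
    "ResamplePlan",
    "EvalReport",
    "accuracy_and_error",
    "effectiveness",
    "union_stability",
    "independent_stability",
    "similarity",
    "make_resamples",
    "fold_indices",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class NestedSubsets:
    """A strictly nested chain S_1 c S_2 c ... with |S_k| = k."""

    chain: list

    def __post_init__(self) -> None:
        prev: set = set()
        for k, s in enumerate(self.chain, start=1):
            s = set(s)
            if len(s) != k or not prev < s:
                raise ValueError("chain must be strictly nested with |S_k| = k")
            prev = s

    @classmethod
    def from_ranking(cls, ranked: Sequence[str], length: int) -> "NestedSubsets":
        ranked = list(ranked)[:length]
        return cls(chain=[ranked[:k] for k in range(1, len(ranked) + 1)])


@dataclass
class ResamplePlan:
    subsamples: list  # k arrays of sample indices
    fraction: float
    seed: int


@dataclass
class EvalReport:
    per_k_accuracy: list
    mean_effectiveness: float
    max_effectiveness: float
    union_stability: Optional[float] = None
    independent_stability: Optional[float] = None
    similarity_mean: Optional[float] = None
    plan: Optional[ResamplePlan] = None


def accuracy_and_error(c: ConfusionCounts) -> tuple:
    """(accuracy, classification error); they sum to 1."""
    if c.total == 0:
        raise ValueError("confusion counts sum to zero")
    acc = (c.TP + c.TN) / c.total
    return acc, (c.FN + c.FP) / c.total


def union_stability(sets: Sequence) -> float:
    """|global intersection| / |global union| of the k selected sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two feature sets")
    union = set.union(*sets)
    if not union:
        raise ValueError("union of feature sets is empty")
    return len(set.intersection(*sets)) / len(union)


def independent_stability(sets: Sequence) -> float:
    """Mean pairwise Jaccard similarity over the k selected sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two feature sets")
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            u = sets[i] | sets[j]
            if not u:
                warnings.warn("empty pair union contributes 0 to independent stability", stacklevel=2)
                vals.append(0.0)
            else:
                vals.append(len(sets[i] & sets[j]) / len(u))
    return float(np.mean(vals))


def similarity(target: Sequence, others: Sequence) -> float:
    """Mean intersection size between the target set and each other set."""
    if len(others) < 1:
        raise ValueError("need at least one other feature set")
    t = set(target)
    return float(np.mean([len(t & set(o)) for o in others]))


def make_resamples(ds: ExpressionDataset, k: int, fraction: float, seed: int) -> ResamplePlan:
    """k without-replacement subsamples of ceil(fraction * n) samples.

    Paired samples are drawn as pairs, so each subsample keeps its class
    balance and no subject is split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if k < 2:
        raise ValueError("need k >= 2 resamples")
    rng = np.random.default_rng(seed)
    subsamples = []
    if ds.pair_ids is not None:
        keys = list(dict.fromkeys(ds.pair_ids))
        take = math.ceil(fraction * len(keys))
        members: dict = {}
        for i, key in enumerate(ds.pair_ids):
            members.setdefault(key, []).append(i)
        for _ in range(k):
            chosen = rng.choice(len(keys), size=take, replace=False)
            idx = sorted(i for c in chosen for i in members[keys[c]])
            subsamples.append(np.array(idx, dtype=int))
    else:
        take = math.ceil(fraction * ds.n_samples)
        for _ in range(k):
            subsamples.append(np.sort(rng.choice(ds.n_samples, size=take, replace=False)))
    for idx in subsamples:
        ysub = ds.y[idx]
        if (ysub > 0).sum() < 2 or (ysub < 0).sum() < 2:
            raise ValueError("subsample has fewer than 2 samples in a class; raise the fraction")
    return ResamplePlan(subsamples=subsamples, fraction=fraction, seed=seed)


def fold_indices(ds: ExpressionDataset, folds: int, seed: int) -> list:
    """Stratified CV folds; paired samples always share a fold."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if ds.pair_ids is not None:
        keys = list(dict.fromkeys(ds.pair_ids))
        if len(keys) < folds:
            raise ValueError("fewer pairs than folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(keys))
        members: dict = {}
        for i, key in enumerate(ds.pair_ids):
            members.setdefault(key, []).append(i)
        out = []
        for f in range(folds):
            test_keys = [keys[perm[i]] for i in range(f, len(keys), folds)]
            test = sorted(i for key in test_keys for i in members[key])
            train = sorted(set(range(ds.n_samples)) - set(test))
            out.append((np.array(train, dtype=int), np.array(test, dtype=int)))
        return out
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    return [(tr, te) for tr, te in skf.split(np.zeros(ds.n_samples), ds.y)]


def _fold_accuracy_mkl(ds, feat_idx, train, test, bank, s, zscore, normalize) -> float:
    Xtr = ds.X[np.ix_(feat_idx, train)].T
    Xte = ds.X[np.ix_(feat_idx, test)].T
    if zscore:
        stats = zscore_fit(Xtr)
        Xtr = zscore_apply(Xtr, stats)
        Xte = zscore_apply(Xte, stats)
    stack = build_stack(Xtr, bank, normalize=normalize)
    model = solve_simplemkl(stack, ds.y[train], s)
    cross = build_cross_stack(Xtr, Xte, stack)
    pred = predict(model, stack, cross)
    return float(np.mean(pred == ds.y[test]))


def _fold_accuracy_linear(ds, feat_idx, train, test, s, zscore) -> float:
    Xtr = ds.X[np.ix_(feat_idx, train)].T
    Xte = ds.X[np.ix_(feat_idx, test)].T
    if zscore:
        stats = zscore_fit(Xtr)
        Xtr = zscore_apply(Xtr, stats)
        Xte = zscore_apply(Xte, stats)
    clf = SVC(kernel="linear", C=s.C)
    clf.fit(Xtr, ds.y[train])
    return float(np.mean(clf.predict(Xte) == ds.y[test]))


def subset_cv_accuracy(
    ds: ExpressionDataset,
    features: Sequence[str],
    folds: int = 10,
    s: SolverSettings = SolverSettings(),
    seed: int = 0,
    bank: Optional[Sequence[KernelSpec]] = None,
    classifier: str = "mkl",
    zscore: bool = True,
    normalize: bool = True,
) -> float:
    """Stratified CV accuracy of the classifier restricted to one feature set."""
    bank = list(bank) if bank is not None else default_kernel_bank()
    feat_idx = ds.feature_index(list(features))
    accs = []
    for train, test in fold_indices(ds, folds, seed):
        if classifier == "linear":
            accs.append(_fold_accuracy_linear(ds, feat_idx, train, test, s, zscore))
        else:
            accs.append(_fold_accuracy_mkl(ds, feat_idx, train, test, bank, s, zscore, normalize))
    return float(np.mean(accs))


def effectiveness(
    ds: ExpressionDataset,
    chain: NestedSubsets,
    folds: int = 10,
    s: SolverSettings = SolverSettings(),
    seed: int = 0,
    bank: Optional[Sequence[KernelSpec]] = None,
    classifier: str = "mkl",
    zscore: bool = True,
    normalize: bool = True,
) -> tuple:
    """CV accuracy over a nested chain of feature sets.

    Returns ``(mean_eff, max_eff, per_k)``. The classifier is the learned
    multiple-kernel predictor by default; ``classifier="linear"`` swaps in a
    plain linear SVM for speed.
    """
    bank = list(bank) if bank is not None else default_kernel_bank()
    splits = fold_indices(ds, folds, seed)
    per_k = []
    for S_k in chain.chain:
        feat_idx = ds.feature_index(list(S_k))
        accs = []
        for train, test in splits:
            if len(np.unique(ds.y[train])) < 2:
                raise ValueError("a CV fold lost a class; use stratified folds or fewer folds")
            if classifier == "linear":
                accs.append(_fold_accuracy_linear(ds, feat_idx, train, test, s, zscore))
            else:
                accs.append(_fold_accuracy_mkl(ds, feat_idx, train, test, bank, s, zscore, normalize))
        per_k.append(float(np.mean(accs)))
    return float(np.mean(per_k)), float(np.max(per_k)), per_k
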