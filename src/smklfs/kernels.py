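"""Base kernel construction and convex combination for expression data.

A multiple-kernel SVM operates on a bank of Gram matrices computed over the
same samples (here: over a chosen subset of expression features), mixed by a
weight vector ``d`` on the probability simplex:

    K(x_i, x_j) = sum_m d_m K_m(x_i, x_j),   d_m >= 0, sum_m d_m = 1.

This module builds and validates the individual Gram matrices, trace-normalizes
them so no kernel family dominates the mixture purely by scale, and forms the
convex combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "GramStack",
    "KernelWeights",
    "compute_gram",
    "compute_cross_gram",
    "default_kernel_bank",
    "combine",
    "normalize_gram",
    "build_stack",
    "build_cross_stack",
    "zscore_fit",
    "zscore_apply",
    "is_psd",
]

_FAMILIES = ("linear", "rbf", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """One base kernel.

    family
        ``linear``: K(u, v) = <u, v>.
        ``rbf``: K(u, v) = exp(-||u - v||^2 / (2 * rbf_bandwidth)).
        ``polynomial``: K(u, v) = (<u, v> + poly_offset) ** poly_degree.
    Fields irrelevant to the chosen family are stored but ignored.
    """

    family: str
    rbf_bandwidth: float = 1.0
    poly_degree: int = 2
    poly_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "rbf" and not self.rbf_bandwidth > 0:
            raise ValueError("rbf_bandwidth must be > 0")
        if self.family == "polynomial" and self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")


@dataclass
class GramMatrix:
    """A square symmetric PSD kernel matrix over n samples.

    ``scale`` records the multiplicative factor applied by trace
    normalization; cross-kernel blocks against new samples must be multiplied
    by the same factor to stay consistent with the training Gram.
    """

    values: np.ndarray
    spec: Optional[KernelSpec] = None
    feature_subset: tuple = ()
    scale: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gram matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("Gram matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10 * max(1.0, float(np.abs(v).max()))):
            raise ValueError("Gram matrix is not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GramStack:
    """An ordered bank of M base Gram matrices over identical samples."""

    mats: list

    def __post_init__(self) -> None:
        if len(self.mats) < 1:
            raise ValueError("GramStack needs at least one kernel")
        n = self.mats[0].n
        fs = self.mats[0].feature_subset
        for g in self.mats[1:]:
            if g.n != n:
                raise ValueError("all Gram matrices in a stack must share sample dimension")
            if g.feature_subset != fs:
                raise ValueError("all Gram matrices in a stack must share the feature subset")

    @property
    def M(self) -> int:
        return len(self.mats)

    @property
    def n(self) -> int:
        return self.mats[0].n


@dataclass
class KernelWeights:
    """Simplex weights d over the kernel bank: d >= 0, sum(d) = 1."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(d < -1e-12):
            raise ValueError("kernel weights must be nonnegative")
        if abs(d.sum() - 1.0) > 1e-8:
            raise ValueError("kernel weights must sum to 1")
        self.d = np.clip(d, 0.0, None)


def _check_finite(X: np.ndarray, feature_ids: Optional[Sequence[str]] = None) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.argwhere(bad.any(axis=0))[0][0])
        name = feature_ids[j] if feature_ids is not None else f"column {j}"
        if np.isnan(X[:, j]).any():
            raise ValueError(f"missing values present in feature {name}")
        raise ValueError(f"non-finite values present in feature {name}")


def compute_gram(X_sub: np.ndarray, spec: KernelSpec, feature_ids: Optional[Sequence[str]] = None) -> GramMatrix:
    """Gram matrix of ``spec`` over the rows (samples) of ``X_sub``.

    ``X_sub`` is sample-by-feature; missing or non-finite values raise with the
    offending feature named.
    """
    X = np.atleast_2d(np.asarray(X_sub, dtype=float))
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("need at least one sample and one feature")
    _check_finite(X, feature_ids)
    inner = X @ X.T
    if spec.family == "linear":
        vals = inner
    elif spec.family == "rbf":
        sq = np.diag(inner)[:, None] + np.diag(inner)[None, :] - 2.0 * inner
        np.clip(sq, 0.0, None, out=sq)
        vals = np.exp(-sq / (2.0 * spec.rbf_bandwidth))
    else:  # polynomial
        vals = (inner + spec.poly_offset) ** spec.poly_degree
    vals = 0.5 * (vals + vals.T)  # exact symmetry despite float noise
    subset = tuple(feature_ids) if feature_ids is not None else ()
    return GramMatrix(values=vals, spec=spec, feature_subset=subset)


def compute_cross_gram(X_train: np.ndarray, X_test: np.ndarray, spec: KernelSpec, scale: float = 1.0) -> np.ndarray:
    """Train-by-test kernel block, scaled consistently with the training Gram."""
    A = np.atleast_2d(np.asarray(X_train, dtype=float))
    B = np.atleast_2d(np.asarray(X_test, dtype=float))
    _check_finite(A)
    _check_finite(B)
    inner = A @ B.T
    if spec.family == "linear":
        vals = inner
    elif spec.family == "rbf":
        sq = (A * A).sum(axis=1)[:, None] + (B * B).sum(axis=1)[None, :] - 2.0 * inner
        np.clip(sq, 0.0, None, out=sq)
        vals = np.exp(-sq / (2.0 * spec.rbf_bandwidth))
    else:
        vals = (inner + spec.poly_offset) ** spec.poly_degree
    return scale * vals


def default_kernel_bank() -> list:
    """The three-kernel bank: linear, RBF with denominator 2, quadratic polynomial."""
    return [
        KernelSpec(family="linear"),
        KernelSpec(family="rbf", rbf_bandwidth=1.0),
        KernelSpec(family="polynomial", poly_degree=2, poly_offset=1.0),
    ]


def combine(stack: GramStack, w: KernelWeights) -> GramMatrix:
    """Convex combination sum_m d_m K_m of the stack's base kernels."""
    if len(w.d) != stack.M:
        raise ValueError(f"weight length {len(w.d)} does not match stack size {stack.M}")
    vals = np.zeros_like(stack.mats[0].values)
    for dm, g in zip(w.d, stack.mats):
        if dm != 0.0:
            vals += dm * g.values
    return GramMatrix(values=vals, spec=None, feature_subset=stack.mats[0].feature_subset)


def normalize_gram(g: GramMatrix) -> GramMatrix:
    """Rescale so the trace equals the sample count n.

    Makes base kernels commensurable before convex weighting; records the
    factor in ``scale`` for consistent cross-kernel blocks.
    """
    tr = float(np.trace(g.values))
    if tr <= 0:
        raise ValueError("cannot trace-normalize a Gram matrix with nonpositive trace")
    factor = g.n / tr
    return GramMatrix(values=g.values * factor, spec=g.spec, feature_subset=g.feature_subset, scale=g.scale * factor)


def zscore_fit(X_train: np.ndarray) -> tuple:
    """Per-feature mean and standard deviation fit on training samples.

    Zero-variance features get unit scale so they map to an (uninformative)
    constant zero rather than NaN.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def zscore_apply(X: np.ndarray, stats: tuple) -> np.ndarray:
    mu, sd = stats
    return (X - mu) / sd


def build_stack(
    X_sub: np.ndarray,
    bank: Sequence[KernelSpec],
    feature_ids: Optional[Sequence[str]] = None,
    normalize: bool = True,
) -> GramStack:
    """Compute the full bank of Gram matrices for one feature subset."""
    mats = []
    for spec in bank:
        g = compute_gram(X_sub, spec, feature_ids=feature_ids)
        if normalize:
            g = normalize_gram(g)
        mats.append(g)
    return GramStack(mats=mats)


def build_cross_stack(X_train: np.ndarray, X_test: np.ndarray, stack: GramStack) -> list:
    """Train-by-test blocks matching each base kernel of a training stack."""
    return [compute_cross_gram(X_train, X_test, g.spec, scale=g.scale) for g in stack.mats]


def is_psd(g: GramMatrix, rtol: float = 1e-8) -> bool:
    """True if the smallest eigenvalue is >= -rtol * trace-scale."""
    w = np.linalg.eigvalsh(g.values)
    tol = rtol * max(float(np.trace(g.values)) / g.n, 1.0)
    return bool(w[0] >= -tol)
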