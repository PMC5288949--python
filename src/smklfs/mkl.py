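"""SVM dual solver and the SimpleMKL saddle-point optimizer.

The soft-margin SVM dual for a fixed Gram matrix K is the concave QP

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C,

with optimum W(a, d) when K = sum_m d_m K_m. SimpleMKL minimizes
J(d) = max_a W(a, d) over the probability simplex by alternating the inner QP
(at fixed weights) with a reduced-gradient descent step on d. By Danskin's
theorem the gradient of J in d_m at the inner optimum a* is

    dJ/dd_m = -1/2 a*^T (y y^T o K_m) a*,

which drives the descent. Smaller J means the classes are easier to separate
in the combined kernel — the quantity the feature-selection stages rank by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.svm import SVC

from .kernels import GramMatrix, GramStack, KernelWeights, combine

__all__ = [
    "SolverSettings",
    "DualSolution",
    "MKLModel",
    "solve_svm_dual",
    "compute_bias",
    "mkl_gradient",
    "solve_simplemkl",
    "predict",
]


@dataclass(frozen=True)
class SolverSettings:
    """Tunables of the inner QP and the outer weight descent.

    C
        Soft-margin box constraint on the dual variables.
    dual_gap_tol
        Relative change in J below which the outer loop stops.
    max_outer_iter
        Cap on outer (weight-update) iterations.
    qp_tol
        KKT residual tolerance passed to the inner QP.
    seed
        Governs any stochastic harness around the solver; the solver itself
        is deterministic.
    """

    C: float = 1.0
    dual_gap_tol: float = 1e-3
    max_outer_iter: int = 200
    qp_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if not (self.dual_gap_tol > 0 and self.qp_tol > 0):
            raise ValueError("tolerances must be > 0")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")


@dataclass
class DualSolution:
    alpha: np.ndarray
    bias: float
    dual_objective: float
    support_indices: np.ndarray


@dataclass
class MKLModel:
    weights: KernelWeights
    dual: DualSolution
    J: float
    n_outer_iter: int
    converged: bool
    y_train: Optional[np.ndarray] = None
    J_history: list = field(default_factory=list)  # J after each outer iteration


def _gram_values(K: Union[GramMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(K, GramMatrix):
        return K.values
    return np.asarray(K, dtype=float)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def _check_psd(K: np.ndarray) -> None:
    n = K.shape[0]
    jitter = 1e-7 * (np.trace(K) / n + 1.0)
    try:
        np.linalg.cholesky(K + jitter * np.eye(n))
    except np.linalg.LinAlgError:
        raise ValueError("kernel matrix is not positive semidefinite beyond tolerance")


def dual_objective_value(alpha: np.ndarray, K: np.ndarray, y: np.ndarray) -> float:
    """W(a, d) = sum a - 1/2 (a o y)^T K (a o y)."""
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def solve_svm_dual(K: Union[GramMatrix, np.ndarray], y: Sequence[float], s: SolverSettings) -> DualSolution:
    """Solve the soft-margin SVM dual on a precomputed Gram matrix.

    The QP itself is delegated to libsvm (precomputed-kernel mode); the dual
    variables, objective and bias are reconstructed from its solution so that
    every reported quantity follows the closed-form definitions above.
    """
    Kv = _gram_values(K)
    y = _check_labels(y)
    n = Kv.shape[0]
    if Kv.shape != (n, n) or len(y) != n:
        raise ValueError("Gram matrix and labels have inconsistent shapes")
    _check_psd(Kv)

    svc = SVC(kernel="precomputed", C=s.C, tol=min(s.qp_tol, 1e-6), shrinking=True, cache_size=64)
    svc.fit(Kv, y)
    alpha = np.zeros(n)
    # libsvm's dual_coef_ stores a_i * y_i on the support vectors
    alpha[svc.support_] = svc.dual_coef_[0] * y[svc.support_]
    alpha = np.clip(alpha, 0.0, s.C)

    obj = dual_objective_value(alpha, Kv, y)
    b = compute_bias(alpha, Kv, y)
    support = np.flatnonzero(alpha > 1e-8 * s.C)
    return DualSolution(alpha=alpha, bias=b, dual_objective=obj, support_indices=support)


def compute_bias(alpha: np.ndarray, K: Union[GramMatrix, np.ndarray], y: Sequence[float]) -> float:
    """Bias placing the decision boundary midway between the class margins:

    b = -1/2 [ max_{i: y_i=-1} f0(x_i) + min_{i: y_i=+1} f0(x_i) ],

    with f0(x_i) = sum_j a_j y_j K(x_i, x_j) the bias-free decision value.
    """
    Kv = _gram_values(K)
    y = _check_labels(y)
    raw = Kv @ (np.asarray(alpha, dtype=float) * y)
    neg = raw[y == -1]
    pos = raw[y == +1]
    return float(-0.5 * (neg.max() + pos.min()))


def mkl_gradient(alpha: np.ndarray, y: Sequence[float], stack: GramStack) -> np.ndarray:
    """Gradient of the dual objective in the kernel weights at fixed alpha."""
    y = np.asarray(y, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if len(alpha) != stack.n or len(y) != stack.n:
        raise ValueError("alpha/label length does not match the Gram dimension")
    ay = alpha * y
    return np.array([-0.5 * ay @ g.values @ ay for g in stack.mats])


def _descent_direction(d: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced-gradient direction on the simplex.

    The largest-weight coordinate is the reference; coordinates pinned at zero
    whose reduced gradient points outward stay at zero.
    """
    mu = int(np.argmax(d))
    D = np.zeros_like(d)
    for m in range(len(d)):
        if m == mu:
            continue
        red = grad[m] - grad[mu]
        if d[m] <= 1e-12 and red > 0:
            D[m] = 0.0
        else:
            D[m] = -red
    D[mu] = -np.sum(D) + D[mu]  # D[mu] currently 0; direction sums to zero
    return D


def solve_simplemkl(stack: GramStack, y: Sequence[float], s: SolverSettings) -> MKLModel:
    """Minimize J(d) = max_a W(a, d) over the simplex.

    Alternates the inner QP at fixed weights with an Armijo-backtracked
    reduced-gradient step (factor 0.5, up to 20 halvings). J never increases
    across outer iterations; non-convergence within ``max_outer_iter`` is
    reported via ``converged=False``, not an error.
    """
    y = _check_labels(y)
    M = stack.M
    d = np.full(M, 1.0 / M)

    def qp_at(dd: np.ndarray) -> DualSolution:
        return solve_svm_dual(combine(stack, KernelWeights(dd)), y, s)

    dual = qp_at(d)
    J = dual.dual_objective
    history = [J]
    converged = False
    n_iter = 0

    for n_iter in range(1, s.max_outer_iter + 1):
        grad = mkl_gradient(dual.alpha, y, stack)
        D = _descent_direction(d, grad)
        if np.max(np.abs(D)) < 1e-12:
            converged = True
            break
        neg = D < -1e-16
        gamma_max = float(np.min(-d[neg] / D[neg]))
        slope = float(grad @ D)
        if slope >= -1e-14:
            converged = True
            break

        gamma = gamma_max
        accepted = False
        for _ in range(20):
            d_try = np.clip(d + gamma * D, 0.0, None)
            d_try /= d_try.sum()
            dual_try = qp_at(d_try)
            if dual_try.dual_objective <= J + 1e-4 * gamma * slope:
                accepted = True
                break
            gamma *= 0.5
        if not accepted:
            converged = True  # no admissible decrease: treat as stationary
            break

        d, dual = d_try, dual_try
        J_new = dual.dual_objective
        history.append(J_new)
        if abs(J - J_new) <= s.dual_gap_tol * max(abs(J), 1e-12):
            J = J_new
            converged = True
            break
        J = J_new

    return MKLModel(
        weights=KernelWeights(d),
        dual=dual,
        J=dual.dual_objective,
        n_outer_iter=n_iter,
        converged=converged,
        y_train=y,
        J_history=history,
    )


def predict(model: MKLModel, stack_train: GramStack, cross_grams: Sequence[np.ndarray]) -> np.ndarray:
    """Labels of new points from the learned mixture.

    ``cross_grams`` are train-by-test blocks, one per base kernel, computed
    with the same specs, feature subset and trace scaling as the training
    stack. The decision value at zero maps to +1.
    """
    if len(cross_grams) != stack_train.M:
        raise ValueError("need one cross-kernel block per base kernel")
    n = stack_train.n
    for cg in cross_grams:
        if cg.shape[0] != n:
            raise ValueError("cross-kernel block rows must match the training samples")
    if model.y_train is None:
        raise ValueError("model carries no training labels")
    Kx = np.zeros_like(cross_grams[0], dtype=float)
    for dm, cg in zip(model.weights.d, cross_grams):
        Kx += dm * cg
    f = (model.dual.alpha * model.y_train) @ Kx + model.dual.bias
    return np.where(f >= 0, 1.0, -1.0)
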