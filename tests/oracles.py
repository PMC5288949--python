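"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the QP oracle is a
generic active-set solve (warm-started by scipy's trust-constr) rather than
libsvm, and the greedy oracle re-enumerates every candidate subset with full
Gram recomputation rather than the incremental accumulators.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def svm_dual_qp_oracle(K: np.ndarray, y: np.ndarray, C: float) -> tuple:
    """Solve max_a 1'a - 1/2 a'Qa s.t. y'a = 0, 0 <= a <= C to high accuracy.

    Generic convex-QP route: interior-point (trust-constr) to locate the
    active set, then exact KKT solves with single-variable active-set
    exchanges until the KKT conditions hold. Returns (alpha, objective).
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    res = minimize(
        lambda a: -(a.sum() - 0.5 * a @ Q @ a),
        np.full(n, C / 2),
        jac=lambda a: -(1.0 - Q @ a),
        hess=lambda a: Q,
        bounds=[(0.0, C)] * n,
        constraints=[LinearConstraint(y, 0.0, 0.0)],
        method="trust-constr",
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    a0 = np.clip(res.x, 0.0, C)
    eps = 1e-5 * C
    state = np.zeros(n, dtype=int)  # 0 free, -1 at lower bound, +1 at upper
    state[a0 <= eps] = -1
    state[a0 >= C - eps] = +1
    tol = 1e-10 * max(1.0, C)

    a = a0.copy()
    lam = 0.0
    for _ in range(50 * n):
        free = state == 0
        a = np.where(state == +1, C, 0.0)
        if free.any():
            yf = y[free]
            Qff = Q[np.ix_(free, free)]
            rhs = 1.0 - Q[np.ix_(free, ~free)] @ a[~free]
            kkt = np.block([[Qff, yf[:, None]], [yf[None, :], np.zeros((1, 1))]])
            target = np.concatenate([rhs, [-y[~free] @ a[~free]]])
            sol = np.linalg.lstsq(kkt, target, rcond=None)[0]
            af, lam = sol[:-1], float(sol[-1])
            # infeasible free variable: pin the worst one and re-solve
            lo_viol = af < -tol
            hi_viol = af > C + tol
            if lo_viol.any() or hi_viol.any():
                idx_free = np.flatnonzero(free)
                viol = np.maximum(-af, af - C)
                worst = int(np.argmax(viol))
                state[idx_free[worst]] = -1 if af[worst] < C / 2 else +1
                continue
            a[free] = np.clip(af, 0.0, C)
        else:
            grad = Q @ a - 1.0
            bounds_lam = [(-grad[i] / y[i], None) if (state[i] == -1) == (y[i] > 0) else (None, -grad[i] / y[i]) for i in range(n)]
            los = [b[0] for b in bounds_lam if b[0] is not None]
            his = [b[1] for b in bounds_lam if b[1] is not None]
            lam = 0.5 * ((max(los) if los else -1e30) + (min(his) if his else 1e30))
        # KKT sign conditions on the bound variables
        g = Q @ a - 1.0 + lam * y
        release = None
        worst_v = tol
        for i in range(n):
            if state[i] == -1 and g[i] < -worst_v:
                release, worst_v = i, -g[i]
            elif state[i] == +1 and g[i] > worst_v:
                release, worst_v = i, g[i]
        if release is None:
            break
        state[release] = 0
    obj = float(a.sum() - 0.5 * a @ Q @ a)
    return a, obj


def greedy_forward_oracle(ds, candidates, bank, settings, r_max, subset_objective) -> tuple:
    """Exhaustive greedy reference for stage 2.

    At every round, recompute J for each remaining candidate with the given
    (full-recomputation) subset objective; accept the best strictly improving
    candidate, earliest-candidate tie-break. Returns (Z, J_seq).
    """
    remaining = list(candidates)
    Z, J_seq = [], []
    J_prev = math.inf
    while remaining and len(Z) < r_max:
        best_J, best_i = math.inf, None
        for i, f in enumerate(remaining):
            J = subset_objective(ds, Z + [f], bank, settings)
            if J < best_J:
                best_J, best_i = J, i
        if best_i is None or not best_J < J_prev:
            break
        Z.append(remaining.pop(best_i))
        J_seq.append(best_J)
        J_prev = best_J
    return Z, J_seq
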