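import numpy as np
import pytest

from oracles import svm_dual_qp_oracle
from smklfs.kernels import (
    GramMatrix,
    GramStack,
    KernelSpec,
    KernelWeights,
    build_cross_stack,
    build_stack,
    combine,
    compute_gram,
    default_kernel_bank,
)
from smklfs.mkl import (
    SolverSettings,
    compute_bias,
    mkl_gradient,
    predict,
    solve_simplemkl,
    solve_svm_dual,
)


def two_point_instance():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1.0, 1.0])
    K = compute_gram(X, KernelSpec("linear"))
    return X, y, K


def random_instance(rng, n=20, p=3, C=1.0):
    X = rng.normal(size=(n, p))
    y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
    rng.shuffle(y)
    stack = build_stack(X, default_kernel_bank())
    return X, y, stack


class TestSvmDual:
    def test_two_point_closed_form(self):
        _, y, K = two_point_instance()
        sol = solve_svm_dual(K, y, SolverSettings(C=10.0))
        assert sol.alpha == pytest.approx([0.5, 0.5], abs=1e-6)
        assert sol.bias == pytest.approx(0.0, abs=1e-6)
        assert sol.dual_objective == pytest.approx(0.5, abs=1e-6)

    def test_box_collapse_as_C_vanishes(self, rng):
        _, y, stack = random_instance(rng)
        K = combine(stack, KernelWeights(np.full(3, 1 / 3)))
        C = 1e-9
        sol = solve_svm_dual(K, y, SolverSettings(C=C))
        assert np.all(sol.alpha <= C + 1e-15)
        # W <= sum(alpha) <= n*C, so the objective collapses with the box
        assert 0.0 <= sol.dual_objective <= len(y) * C * (1 + 1e-9)

    def test_matches_generic_qp_oracle(self, rng):
        for _ in range(10):
            _, y, stack = random_instance(rng)
            K = combine(stack, KernelWeights(np.full(3, 1 / 3)))
            sol = solve_svm_dual(K, y, SolverSettings(C=1.0))
            a_star, w_star = svm_dual_qp_oracle(K.values, y, 1.0)
            assert np.abs(sol.alpha - a_star).max() < 1e-4
            assert sol.dual_objective == pytest.approx(w_star, abs=1e-6)

    def test_alpha_satisfies_constraints(self, rng):
        _, y, stack = random_instance(rng, n=30)
        K = combine(stack, KernelWeights(np.full(3, 1 / 3)))
        s = SolverSettings(C=2.0)
        sol = solve_svm_dual(K, y, s)
        assert np.all(sol.alpha >= 0) and np.all(sol.alpha <= s.C + 1e-6)
        assert abs(sol.alpha @ y) <= 1e-6 * s.C * len(y)

    def test_single_class_rejected(self):
        K = GramMatrix(np.eye(4))
        with pytest.raises(ValueError, match="both classes"):
            solve_svm_dual(K, np.ones(4), SolverSettings())

    def test_indefinite_kernel_rejected(self):
        K = np.diag([1.0, -5.0, 1.0, 1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="positive semidefinite"):
            solve_svm_dual(K, y, SolverSettings())


class TestBias:
    def test_two_point_bias_zero(self):
        _, y, K = two_point_instance()
        sol = solve_svm_dual(K, y, SolverSettings(C=10.0))
        assert compute_bias(sol.alpha, K, y) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_symmetric_instance(self, rng):
        X_half = rng.normal(size=(8, 2)) + 2.0
        X = np.vstack([X_half, -X_half])
        y = np.array([1.0] * 8 + [-1.0] * 8)
        K = compute_gram(X, KernelSpec("linear"))
        sol = solve_svm_dual(K, y, SolverSettings(C=1.0))
        assert compute_bias(sol.alpha, K, y) == pytest.approx(0.0, abs=1e-6)

    def test_score_shift_moves_bias_oppositely(self, rng):
        _, y, stack = random_instance(rng, n=12)
        K = combine(stack, KernelWeights(np.full(3, 1 / 3)))
        sol = solve_svm_dual(K, y, SolverSettings(C=1.0))
        b0 = compute_bias(sol.alpha, K, y)
        delta = 0.37
        ay = sol.alpha * y
        # rank-one offset engineered so every raw score shifts by exactly +delta
        shift = delta * np.outer(np.ones(len(y)), ay) / (ay @ ay)
        b1 = compute_bias(sol.alpha, K.values + shift, y)
        assert b1 == pytest.approx(b0 - delta, abs=1e-9)


class TestGradient:
    def test_zero_alpha_gives_zero_gradient(self, rng):
        _, y, stack = random_instance(rng, n=10)
        g = mkl_gradient(np.zeros(10), y, stack)
        assert np.allclose(g, 0.0)

    def test_identical_kernels_equal_components(self, rng):
        X = rng.normal(size=(10, 2))
        g1 = compute_gram(X, KernelSpec("rbf"))
        stack = GramStack(mats=[g1, g1, g1])
        y = np.array([1.0] * 5 + [-1.0] * 5)
        alpha = rng.random(10)
        g = mkl_gradient(alpha, y, stack)
        assert np.allclose(g, g[0])

    def test_matches_finite_differences_of_inner_optimum(self, rng):
        s = SolverSettings(C=1.0, qp_tol=1e-10)
        for _ in range(3):
            _, y, stack = random_instance(rng, n=30, p=4)
            d0 = np.array([0.5, 0.3, 0.2])
            sol = solve_svm_dual(combine(stack, KernelWeights(d0)), y, s)
            g = mkl_gradient(sol.alpha, y, stack)
            h = 1e-4
            for m in range(3):
                dd_hi, dd_lo = d0.copy(), d0.copy()
                dd_hi[m] += h
                dd_lo[m] -= h
                K_hi = sum(w * gm.values for w, gm in zip(dd_hi, stack.mats))
                K_lo = sum(w * gm.values for w, gm in zip(dd_lo, stack.mats))
                fd = (
                    solve_svm_dual(K_hi, y, s).dual_objective
                    - solve_svm_dual(K_lo, y, s).dual_objective
                ) / (2 * h)
                assert abs(g[m] - fd) <= 1e-4 * max(abs(fd), 1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        _, y, stack = random_instance(rng, n=10)
        with pytest.raises(ValueError, match="length"):
            mkl_gradient(np.zeros(7), y[:7], stack)


class TestSimpleMKL:
    def test_single_kernel_reduces_to_svm_dual(self, rng):
        for _ in range(10):
            X = rng.normal(size=(16, 3))
            y = np.array([1.0] * 8 + [-1.0] * 8)
            rng.shuffle(y)
            stack = build_stack(X, [KernelSpec("rbf")])
            s = SolverSettings(C=1.0)
            model = solve_simplemkl(stack, y, s)
            direct = solve_svm_dual(stack.mats[0], y, s)
            assert model.J == pytest.approx(direct.dual_objective, abs=1e-8)
            assert model.weights.d == pytest.approx([1.0])

    def test_identical_kernels_match_single_kernel_objective(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1.0] * 10 + [-1.0] * 10)
        g = compute_gram(X, KernelSpec("rbf"))
        s = SolverSettings(C=1.0)
        model = solve_simplemkl(GramStack(mats=[g, g]), y, s)
        single = solve_svm_dual(g, y, s)
        assert model.J == pytest.approx(single.dual_objective, abs=1e-6)

    def test_informative_kernel_outweighs_noise_kernel(self, rng):
        n = 30
        y = np.array([1.0] * 15 + [-1.0] * 15)
        sep = y[:, None] + 0.01 * rng.normal(size=(n, 1))
        noise = rng.normal(size=(n, 1))
        gA = compute_gram(sep, KernelSpec("linear"))
        gB = compute_gram(noise, KernelSpec("linear"))
        s = SolverSettings(C=1.0)
        model = solve_simplemkl(GramStack(mats=[gA, gB]), y, s)
        assert model.weights.d[0] > model.weights.d[1]
        J_B = solve_svm_dual(gB, y, s).dual_objective
        assert model.J < J_B

    def test_objective_never_increases_and_weights_stay_on_simplex(self, rng):
        for _ in range(5):
            _, y, stack = random_instance(rng, n=24)
            model = solve_simplemkl(stack, y, SolverSettings(C=1.0))
            hist = np.array(model.J_history)
            assert np.all(np.diff(hist) <= 1e-8)
            d = model.weights.d
            assert abs(d.sum() - 1.0) <= 1e-8 and np.all(d >= 0)

    def test_objective_invariant_to_sample_permutation(self, rng):
        X, y, stack = random_instance(rng, n=18)
        s = SolverSettings(C=1.0)
        J = solve_simplemkl(stack, y, s).J
        perm = rng.permutation(18)
        stack_p = build_stack(X[perm], default_kernel_bank())
        J_p = solve_simplemkl(stack_p, y[perm], s).J
        assert J_p == pytest.approx(J, rel=1e-6)

    def test_label_noise_rarely_decreases_objective(self, rng):
        n = 30
        base_y = np.array([1.0] * 15 + [-1.0] * 15)
        X = base_y[:, None] + 0.05 * np.random.default_rng(0).normal(size=(n, 2))
        stack = build_stack(X, default_kernel_bank())
        s = SolverSettings(C=1.0)
        J_clean = solve_simplemkl(stack, base_y, s).J
        not_decreased = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = base_y.copy()
            flip = r.choice(n, size=6, replace=False)
            y[flip] *= -1
            if solve_simplemkl(stack, y, s).J >= J_clean - 1e-9:
                not_decreased += 1
        assert not_decreased > 10  # majority direction over 20 seeds


class TestPredict:
    def test_two_point_model_predicts_new_point(self):
        X, y, K = two_point_instance()
        stack = GramStack(mats=[K])
        model = solve_simplemkl(stack, y, SolverSettings(C=10.0))
        cross = build_cross_stack(X, np.array([[2.0]]), stack)
        assert predict(model, stack, cross) == pytest.approx([1.0])

    def test_support_vector_classified_to_its_margin(self):
        X, y, K = two_point_instance()
        stack = GramStack(mats=[K])
        model = solve_simplemkl(stack, y, SolverSettings(C=10.0))
        cross = build_cross_stack(X, np.array([[-1.0]]), stack)
        assert predict(model, stack, cross) == pytest.approx([-1.0])

    def test_degenerate_weights_match_single_kernel_svm(self, rng):
        X, y, _ = (rng.normal(size=(20, 2)), np.array([1.0] * 10 + [-1.0] * 10), None)
        stack = build_stack(X, [KernelSpec("linear")], normalize=False)
        s = SolverSettings(C=1.0)
        model = solve_simplemkl(stack, y, s)
        Xnew = rng.normal(size=(7, 2))
        cross = build_cross_stack(X, Xnew, stack)
        pred = predict(model, stack, cross)
        f = (model.dual.alpha * y) @ (X @ Xnew.T) + model.dual.bias
        assert np.array_equal(pred, np.where(f >= 0, 1.0, -1.0))

    def test_cross_block_shape_mismatch_rejected(self, rng):
        _, y, stack = random_instance(rng, n=10)
        model = solve_simplemkl(stack, y, SolverSettings(C=1.0))
        bad = [np.zeros((9, 2))] * stack.M
        with pytest.raises(ValueError, match="rows"):
            predict(model, stack, bad)
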