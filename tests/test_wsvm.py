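import json

import numpy as np
import pytest
from scipy.optimize import minimize

from rifsvm.datasets import LabeledDataset
from rifsvm.memberships import FuzzyWeights
from rifsvm.wsvm import (
    KernelSpec,
    compute_bias,
    decision_values,
    fit,
    kernel_matrix,
    solve_weighted_dual,
)
from tests.conftest import random_imbalanced_dataset


def random_qp_problem(rng, n_max=30, n_min=6):
    n = int(rng.integers(n_min, n_max + 1))
    X = rng.normal(size=(n, 2))
    y = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    rng.shuffle(y)
    s = rng.uniform(0.2, 1.0, n)
    C = float(rng.choice([0.5, 1.0, 10.0]))
    spec = KernelSpec("rbf", float(rng.uniform(0.3, 2.0)))
    K = kernel_matrix(X, X, spec)
    return X, y, s, C, K, spec


def dense_qp_oracle(K, y, s, C):
    """Independent small-scale solve: SLSQP then exact active-set polish."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    u = s * C
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1,
        bounds=[(0.0, ui) for ui in u],
        constraints=[{"type": "eq", "fun": lambda a: y @ a, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = np.clip(res.x, 0, u)
    free = (a > 1e-7) & (a < u - 1e-7)
    if free.any():
        nf = int(free.sum())
        A = np.zeros((nf + 1, nf + 1))
        rhs = np.zeros(nf + 1)
        A[:nf, :nf] = Q[np.ix_(free, free)]
        A[:nf, nf] = y[free]
        A[nf, :nf] = y[free]
        fixed = ~free
        rhs[:nf] = 1 - Q[np.ix_(free, fixed)] @ a[fixed]
        rhs[nf] = -y[fixed] @ a[fixed]
        try:
            sol = np.linalg.solve(A, rhs)
            cand = a.copy()
            cand[free] = sol[:nf]
            if np.all(cand >= -1e-12) and np.all(cand <= u + 1e-12):
                a = np.clip(cand, 0, u)
        except np.linalg.LinAlgError:
            pass
    return a, float(a.sum() - 0.5 * a @ Q @ a)


class TestKernelMatrix:
    def test_rbf_self_similarity_is_one(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        K = kernel_matrix(X, X, KernelSpec("rbf", 1.0))
        assert np.allclose(np.diag(K), 1.0)

    def test_rbf_flat_limit(self):
        X = np.array([[0.0], [1.0], [2.0]])
        K = kernel_matrix(X, X, KernelSpec("rbf", 1e-12))
        assert np.allclose(K, 1.0, atol=1e-9)

    def test_matches_scalar_loop(self, rng):
        A = rng.normal(size=(5, 3))
        B = rng.normal(size=(4, 3))
        h = 0.7
        K = kernel_matrix(A, B, KernelSpec("rbf", h))
        for i in range(5):
            for j in range(4):
                assert K[i, j] == pytest.approx(np.exp(-h * np.sum((A[i] - B[j]) ** 2)))
        KL = kernel_matrix(A, B, KernelSpec("linear"))
        assert np.allclose(KL, A @ B.T)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            kernel_matrix(np.zeros((2, 3)), np.zeros((2, 4)), KernelSpec("linear"))


class TestSolveWeightedDual:
    def test_two_point_closed_form(self):
        # one point per class, unit weights, hard margin; the dual reduces to
        # maximizing 2a - a^2 ||x1-x2||^2 / 2, so alpha = 2 / ||x1-x2||^2
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, -1.0])
        K = kernel_matrix(X, X, KernelSpec("linear"))
        sol = solve_weighted_dual(K, y, np.ones(2), C=1e6)
        assert np.allclose(sol.alpha, 2.0 / 4.0, atol=1e-8)
        b = compute_bias(sol, K, y)
        f_mid = (sol.alpha * y) @ (X @ np.array([1.0, 0.0])) + b
        assert f_mid == pytest.approx(0.0, abs=1e-8)

    def test_equality_constraint(self, rng):
        for _ in range(5):
            X, y, s, C, K, _ = random_qp_problem(rng)
            sol = solve_weighted_dual(K, y, s, C)
            assert abs(np.sum(y * sol.alpha)) < 1e-6

    def test_objective_matches_dense_qp_oracle(self, rng):
        for _ in range(10):
            X, y, s, C, K, _ = random_qp_problem(rng, n_max=8, n_min=5)
            sol = solve_weighted_dual(K, y, s, C)
            _, obj_ref = dense_qp_oracle(K, y, s, C)
            assert sol.objective == pytest.approx(obj_ref, rel=1e-6, abs=1e-6)

    def test_objective_dominates_random_feasible_points(self, rng):
        X, y, s, C, K, _ = random_qp_problem(rng, n_max=8, n_min=6)
        Q = (y[:, None] * y[None, :]) * K
        u = s * C
        sol = solve_weighted_dual(K, y, s, C)
        for _ in range(1000):
            a = rng.uniform(0, u)
            # project onto the equality constraint along y, then re-clip
            a = np.clip(a - y * (y @ a) / len(y), 0, u)
            a = np.clip(a - y * (y @ a) / len(y), 0, u)
            if abs(y @ a) > 1e-9:
                continue
            assert sol.objective >= a.sum() - 0.5 * a @ Q @ a - 1e-9

    def test_zero_weight_equals_deletion(self, rng):
        ds = random_imbalanced_dataset(rng, n_pos=8, n_neg=15, d=2)
        spec = KernelSpec("rbf", 1.0)
        s = np.ones(ds.n)
        s[3] = 0.0
        m_zeroed = fit(ds, scheme="unit", C=2.0, kernel=spec, weights=FuzzyWeights(s, 1.0, "unit"))
        keep = np.arange(ds.n) != 3
        ds_del = LabeledDataset(ds.X[keep], ds.y[keep])
        m_deleted = fit(ds_del, scheme="unit", C=2.0, kernel=spec)
        probe = np.vstack([ds.X, ds.X + 0.1])
        assert np.allclose(
            m_zeroed.decision_function(probe), m_deleted.decision_function(probe), atol=1e-6
        )

    def test_no_trainable_class_error(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        K = kernel_matrix(X, X, KernelSpec("linear"))
        with pytest.raises(ValueError, match="no trainable"):
            solve_weighted_dual(K, y, np.array([0.0, 0.0, 1.0, 1.0]), C=1.0)

    def test_non_psd_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="not PSD"):
            solve_weighted_dual(K, np.array([1.0, -1.0]), np.ones(2), 1.0, check_psd=True)

    def test_kkt_conditions(self, rng):
        eps = 1e-4
        for _ in range(10):
            X, y, s, C, K, _ = random_qp_problem(rng)
            sol = solve_weighted_dual(K, y, s, C)
            b = compute_bias(sol, K, y)
            f = K @ (sol.alpha * y) + b
            u = s * C
            margin = y * f
            for i in range(len(y)):
                if sol.alpha[i] < 1e-8:
                    assert margin[i] >= 1 - eps
                elif sol.alpha[i] > u[i] - 1e-8:
                    assert margin[i] <= 1 + eps
                else:
                    assert margin[i] == pytest.approx(1.0, abs=eps)


class TestAgainstStandardSVM:
    def test_unit_weights_match_reference_svm(self, rng):
        sklearn = pytest.importorskip("sklearn.svm")
        for _ in range(5):
            ds = random_imbalanced_dataset(rng, n_pos=10, n_neg=25, d=2)
            h, C = 0.5, 10.0
            model = fit(ds, scheme="unit", C=C, kernel=KernelSpec("rbf", h))
            clf = sklearn.SVC(C=C, kernel="rbf", gamma=h, tol=1e-8)
            clf.fit(ds.X, ds.y)
            assert np.allclose(
                model.decision_function(ds.X), clf.decision_function(ds.X), atol=1e-4
            )


class TestBias:
    def test_translation_equivariance_linear_kernel(self, rng):
        ds = random_imbalanced_dataset(rng, n_pos=8, n_neg=12, d=2)
        spec = KernelSpec("linear")
        m1 = fit(ds, scheme="unit", C=1.0, kernel=spec)
        shift = np.array([2.0, -1.0])
        ds2 = LabeledDataset(ds.X + shift, ds.y)
        m2 = fit(ds2, scheme="unit", C=1.0, kernel=spec)
        # identical decision values at corresponding (translated) points
        assert np.allclose(m1.decision_function(ds.X), m2.decision_function(ds.X + shift), atol=1e-5)

    def test_free_sv_margins(self, rng):
        ds = random_imbalanced_dataset(rng, n_pos=10, n_neg=20, d=2)
        model = fit(ds, scheme="unit", C=5.0, kernel=KernelSpec("rbf", 1.0))
        f = model.decision_function(ds.X)
        # reconstruct free SVs: alpha strictly inside (0, C)
        # via the stored dual coefficients (|coef| = alpha for unit weights)
        alpha = np.abs(model.dual_coef)
        free = (alpha > 1e-6) & (alpha < 5.0 - 1e-6)
        sv_f = model.decision_function(model.support_vectors)
        sv_y = np.sign(model.dual_coef)
        assert np.all(np.abs(sv_y[free] * sv_f[free] - 1.0) < 1e-4)


class TestDecisionAndFit:
    def test_far_point_decays_to_bias(self, rng):
        ds = random_imbalanced_dataset(rng, n_pos=6, n_neg=10, d=2)
        model = fit(ds, scheme="unit", C=1.0, kernel=KernelSpec("rbf", 1.0))
        far = np.array([[500.0, 500.0]])
        assert decision_values(model, far)[0] == pytest.approx(model.bias, abs=1e-10)

    def test_unit_scheme_equals_forced_unit_weights_rif_path(self, rng):
        ds = random_imbalanced_dataset(rng, n_pos=10, n_neg=20)
        spec = KernelSpec("rbf", 1.0)
        m_unit = fit(ds, scheme="unit", C=1.0, kernel=spec)
        forced = FuzzyWeights(np.ones(ds.n), ds.imbalance_ratio, "rif")
        m_rif = fit(ds, scheme="rif", C=1.0, kernel=spec, weights=forced)
        assert np.allclose(m_unit.decision_function(ds.X), m_rif.decision_function(ds.X))

    def test_inactive_bound_invariance_under_doubling_C(self, rng):
        # separable data, all alpha strictly interior: doubling C changes nothing
        pos = rng.normal((0, 0), 0.2, size=(10, 2))
        neg = rng.normal((6, 6), 0.2, size=(10, 2))
        ds = LabeledDataset(
            np.vstack([pos, neg]), np.concatenate([np.ones(10, dtype=int), -np.ones(10, dtype=int)])
        )
        m1 = fit(ds, scheme="unit", C=100.0, kernel=KernelSpec("rbf", 0.1))
        alpha_max = np.abs(m1.dual_coef).max()
        assert alpha_max < 100.0 - 1e-6  # bounds inactive
        m2 = fit(ds, scheme="unit", C=200.0, kernel=KernelSpec("rbf", 0.1))
        assert np.allclose(m1.decision_function(ds.X), m2.decision_function(ds.X), atol=1e-5)

    def test_cost_sensitive_reparametrization_equivalence(self, rng):
        # box bounds s_i * C with majority s_i = IR * H_i equal bounds built
        # from class-specific costs C+ = C, C- = IR * C with majority s_i = H_i
        ds = random_imbalanced_dataset(rng, n_pos=8, n_neg=24)
        from rifsvm.memberships import rif_weights

        fw = rif_weights(ds)
        C = 4.0
        spec = KernelSpec("rbf", 1.0)
        K = kernel_matrix(ds.X, ds.X, spec)
        sol1 = solve_weighted_dual(K, ds.y, fw.s, C)
        maj = ds.y == -1
        s_cs = fw.s.copy()
        s_cs[maj] = fw.s[maj] / fw.IR  # back to plain H
        C_per = np.where(maj, fw.IR * C, C)
        # identical upper bounds => identical QP; solve with bounds folded in
        sol2 = solve_weighted_dual(K, ds.y, s_cs * C_per / C, C)
        assert np.allclose(sol1.alpha, sol2.alpha)

    def test_serialization_roundtrip(self, rng):
        from rifsvm.wsvm import TrainedModel

        ds = random_imbalanced_dataset(rng, n_pos=8, n_neg=12)
        model = fit(ds, scheme="rif", C=1.0, kernel=KernelSpec("rbf", 2.0))
        restored = TrainedModel.from_json(model.to_json())
        assert np.allclose(
            model.decision_function(ds.X), restored.decision_function(ds.X)
        )
        assert json.loads(model.to_json())["scheme"] == "rif"
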