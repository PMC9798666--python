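import numpy as np
import pytest

from dtimf import (DomainError, SolverConfig, augmented_lagrangian,
                   auc_score, objective, project_nonneg, project_omega,
                   solve)
from dtimf.solver import (update_M, update_multipliers, update_U, update_V,
                          update_X, update_Y)
from conftest import random_block_state
from oracles import auglag_oracle, objective_oracle


class TestProjections:
    def test_project_omega_full_set_is_identity(self, small_rng):
        A = small_rng.normal(size=(3, 4))
        omega = {(i, j) for i in range(3) for j in range(4)}
        np.testing.assert_array_equal(project_omega(A, A, omega), A)

    def test_project_omega_empty_set_is_zero(self, small_rng):
        A = small_rng.normal(size=(3, 4))
        np.testing.assert_array_equal(project_omega(A, A, set()),
                                      np.zeros((3, 4)))

    def test_project_omega_elementwise(self):
        A = np.array([[3.0, 4.0], [5.0, 6.0]])
        out = project_omega(A, A, {(0, 0), (1, 1)})
        np.testing.assert_array_equal(out, [[3.0, 0.0], [0.0, 6.0]])

    def test_project_omega_shape_mismatch(self):
        with pytest.raises(DomainError):
            project_omega(np.ones((2, 2)), np.ones((3, 2)), set())

    @pytest.mark.parametrize("A,expected", [
        ([[-1.0, -2.0]], [[0.0, 0.0]]),
        ([[1.0, 2.0]], [[1.0, 2.0]]),
        ([[-1.0, 2.0]], [[0.0, 2.0]]),
    ])
    def test_project_nonneg(self, A, expected):
        np.testing.assert_array_equal(project_nonneg(np.array(A)),
                                      np.array(expected))


class TestObjectives:
    def test_exact_factorization_no_reg_is_zero(self, small_rng):
        X = small_rng.uniform(size=(4, 2))
        Y = small_rng.uniform(size=(3, 2))
        val = objective(X, Y, X @ Y.T, np.eye(4), np.eye(3), 0.0, 0.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_zero_factors_give_half_m_norm(self, small_rng):
        M = small_rng.normal(size=(4, 3))
        val = objective(np.zeros((4, 2)), np.zeros((3, 2)), M,
                        np.eye(4), np.eye(3), 1.0, 1.0)
        assert val == pytest.approx(0.5 * np.sum(M**2))

    def test_objective_matches_scalar_loop(self, small_rng):
        for _ in range(5):
            state, config, Ld, Lt = random_block_state(small_rng, 5, 4, 2)
            expected = objective_oracle(state.X, state.Y, state.M, Ld, Lt,
                                        config.lambda_d, config.lambda_t)
            got = objective(state.X, state.Y, state.M, Ld, Lt,
                            config.lambda_d, config.lambda_t)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_auglag_equals_objective_at_feasible_point(self, small_rng):
        state, config, Ld, Lt = random_block_state(small_rng)
        state.U = state.X.copy()
        state.V = state.Y.T.copy()
        assert augmented_lagrangian(state, config, Ld, Lt) == pytest.approx(
            objective(state.X, state.Y, state.M, Ld, Lt,
                      config.lambda_d, config.lambda_t))

    def test_auglag_matches_scalar_loop(self, small_rng):
        for _ in range(5):
            state, config, Ld, Lt = random_block_state(small_rng, 5, 4, 2)
            expected = auglag_oracle(state.X, state.Y, state.M, state.U,
                                     state.V, state.Lambda, state.Pi, Ld, Lt,
                                     config.lambda_d, config.lambda_t,
                                     config.alpha, config.beta)
            got = augmented_lagrangian(state, config, Ld, Lt)
            assert got == pytest.approx(expected, rel=1e-10)


class TestBlockUpdates:
    def test_x_residual_equation(self, small_rng):
        # X_next (Y^T Y + alpha I) must equal the right-hand side exactly
        state, config, Ld, Lt = random_block_state(small_rng)
        X_next = update_X(state, config, Ld)
        k = state.Y.shape[1]
        rhs = (state.M @ state.Y - config.lambda_d * Ld @ state.X
               + config.alpha * state.U - state.Lambda)
        lhs = X_next @ (state.Y.T @ state.Y + config.alpha * np.eye(k))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_y_residual_equation(self, small_rng):
        state, config, Ld, Lt = random_block_state(small_rng)
        Y_next = update_Y(state, config, Lt)
        k = state.X.shape[1]
        rhs = (state.M.T @ state.X - config.lambda_t * Lt @ state.Y
               + config.beta * state.V.T - state.Pi.T)
        lhs = Y_next @ (state.X.T @ state.X + config.beta * np.eye(k))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_x_update_minimizes_against_scipy(self, small_rng):
        # with lambda_d = 0 the X block is a smooth unconstrained quadratic;
        # compare against a generic numerical minimizer
        from scipy.optimize import minimize

        state, config, Ld, Lt = random_block_state(small_rng, 4, 3, 2)
        config = SolverConfig(k=2, lambda_d=0.0, lambda_t=0.0,
                              alpha=config.alpha, beta=config.beta)
        X_next = update_X(state, config, Ld)

        def f(x):
            X = x.reshape(4, 2)
            return (0.5 * np.sum((state.M - X @ state.Y.T) ** 2)
                    + np.sum(state.Lambda * (X - state.U))
                    + 0.5 * config.alpha * np.sum((X - state.U) ** 2))

        res = minimize(f, state.X.ravel(), method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        np.testing.assert_allclose(X_next.ravel(), res.x, atol=1e-5)

    def test_penalty_dominated_limit_pins_x(self, small_rng):
        state, config, Ld, Lt = random_block_state(small_rng)
        state.U = state.X.copy()
        state.Lambda = np.zeros_like(state.Lambda)
        big = SolverConfig(k=2, lambda_d=0.0, lambda_t=0.0, alpha=1e8,
                           beta=config.beta)
        X_next = update_X(state, big, Ld)
        np.testing.assert_allclose(X_next, state.X, atol=1e-6)

    def test_m_update_respects_omega(self, small_rng):
        X = small_rng.normal(size=(4, 2))
        Y = small_rng.normal(size=(3, 2))
        Z = np.zeros((4, 3))
        Z[0, 1] = Z[2, 2] = 1.0
        omega = {(0, 1), (2, 2)}
        M = update_M(X, Y, Z, omega)
        assert M[0, 1] == 1.0 and M[2, 2] == 1.0
        off = ~np.isin(np.arange(12).reshape(4, 3), [1, 8])
        np.testing.assert_array_equal(M[off], (X @ Y.T)[off])

    def test_m_update_empty_omega_is_product(self, small_rng):
        X = small_rng.normal(size=(4, 2))
        Y = small_rng.normal(size=(3, 2))
        M = update_M(X, Y, np.zeros((4, 3)), set())
        np.testing.assert_array_equal(M, X @ Y.T)

    def test_u_v_projections(self, small_rng):
        X = small_rng.normal(size=(4, 2))
        Lam = small_rng.normal(size=(4, 2))
        np.testing.assert_array_equal(update_U(X, Lam, 0.5),
                                      np.maximum(X + Lam / 0.5, 0.0))
        Y = small_rng.normal(size=(3, 2))
        Pi = small_rng.normal(size=(2, 3))
        np.testing.assert_array_equal(update_V(Y, Pi, 0.3),
                                      np.maximum(Y.T + Pi / 0.3, 0.0))

    def test_multiplier_step(self, small_rng):
        state, config, _, _ = random_block_state(small_rng)
        Lam, Pi = update_multipliers(state, config)
        np.testing.assert_allclose(
            Lam, state.Lambda + config.gamma * config.alpha
            * (state.X - state.U))
        np.testing.assert_allclose(
            Pi, state.Pi + config.gamma * config.beta
            * (state.Y.T - state.V))

    def test_multipliers_fixed_at_feasibility(self, small_rng):
        state, config, _, _ = random_block_state(small_rng)
        state.U = state.X.copy()
        state.V = state.Y.T.copy()
        Lam, Pi = update_multipliers(state, config)
        np.testing.assert_array_equal(Lam, state.Lambda)
        np.testing.assert_array_equal(Pi, state.Pi)


class TestSolve:
    def test_rank_one_completion(self):
        # Z = outer product of indicators; its support is exactly recoverable
        u = np.array([1.0, 0.0, 1.0, 1.0])
        v = np.array([0.0, 1.0, 1.0])
        Z = np.outer(u, v)
        config = SolverConfig(k=1, lambda_d=0.0, lambda_t=0.0, seed=0)
        state, trace = solve(Z, Z == 1, np.zeros((4, 4)), np.zeros((3, 3)),
                             config)
        assert state.converged
        assert state.rel_change < config.epsilon
        np.testing.assert_array_equal(state.M[Z == 1], 1.0)

    def test_constraint_exact_at_every_iterate(self, solver_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z = interactions.Z
        seen = []

        def check(state):
            seen.append(state.iteration)
            assert (state.M[Z == 1.0] == 1.0).all()

        config = SolverConfig(k=8, seed=0, max_iter=60)
        solve(Z, Z == 1, gd.L_norm, gt.L_norm, config, callback=check)
        assert len(seen) == 60

    def test_nonnegativity_of_reported_factors(self, solver_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z = interactions.Z

        def check(state):
            assert (state.U >= 0).all() and (state.V >= 0).all()

        config = SolverConfig(k=8, seed=0, max_iter=40)
        solve(Z, Z == 1, gd.L_norm, gt.L_norm, config, callback=check)

    def test_reduces_to_nmf_without_reg_or_constraint(self, small_rng):
        # exactly factorable non-negative matrix, no constraint, no graphs
        W = small_rng.uniform(size=(6, 2))
        H = small_rng.uniform(size=(5, 2))
        Z = W @ H.T
        Z = Z / Z.max()  # keep entries in [0, 1] scale
        config = SolverConfig(k=2, lambda_d=0.0, lambda_t=0.0, seed=1,
                              max_iter=2000, epsilon=1e-12)
        state, trace = solve(Z, np.zeros_like(Z, dtype=bool),
                             np.zeros((6, 6)), np.zeros((5, 5)), config)
        assert trace.objective.iloc[-1] < 1e-6

    def test_determinism(self, solver_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z = interactions.Z
        config = SolverConfig(k=6, seed=3, max_iter=50)
        s1, t1 = solve(Z, Z == 1, gd.L_norm, gt.L_norm, config)
        s2, t2 = solve(Z, Z == 1, gd.L_norm, gt.L_norm, config)
        assert np.array_equal(s1.M, s2.M)
        assert t1.equals(t2)

    def test_k_clamped_with_warning(self, solver_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z = interactions.Z
        config = SolverConfig(k=50, seed=0, max_iter=5)
        with pytest.warns(UserWarning, match="clamping"):
            state, _ = solve(Z, Z == 1, gd.L_norm, gt.L_norm, config)
        assert state.X.shape[1] == min(Z.shape)

    def test_heldout_recovery(self, solver_instance, masked_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z_train, held = masked_instance
        config = SolverConfig(seed=0)
        with pytest.warns(UserWarning, match="clamping"):
            state, _ = solve(Z_train, Z_train == 1, gd.L_norm, gt.L_norm,
                             config)
        neg = np.argwhere(interactions.Z == 0)
        labels = np.r_[np.ones(len(held)), np.zeros(len(neg))]
        scores = np.r_[state.M[held[:, 0], held[:, 1]],
                       state.M[neg[:, 0], neg[:, 1]]]
        assert auc_score(labels, scores) >= 0.9

    def test_svd_init_also_recovers(self, solver_instance, masked_instance):
        interactions, _, _, _, gd, gt = solver_instance
        Z_train, held = masked_instance
        config = SolverConfig(k=8, seed=0, init_scheme="svd-based")
        state, _ = solve(Z_train, Z_train == 1, gd.L_norm, gt.L_norm, config)
        neg = np.argwhere(interactions.Z == 0)
        labels = np.r_[np.ones(len(held)), np.zeros(len(neg))]
        scores = np.r_[state.M[held[:, 0], held[:, 1]],
                       state.M[neg[:, 0], neg[:, 1]]]
        assert auc_score(labels, scores) >= 0.9

    def test_graph_weight_stall_is_slow_but_stable(self, solver_instance):
        # with active graph terms the relative-change metric decays
        # sublinearly: the run hits the cap unconverged, yet the iterates
        # stay finite and the trace change keeps shrinking
        interactions, _, _, _, gd, gt = solver_instance
        Z = interactions.Z
        config = SolverConfig(k=8, seed=0, max_iter=400)
        state, trace = solve(Z, Z == 1, gd.L_norm, gt.L_norm, config)
        assert not state.converged
        assert np.isfinite(state.M).all()
        assert trace.rel_change.iloc[-1] < trace.rel_change.iloc[9]

    def test_bad_config_values_rejected(self):
        with pytest.raises(DomainError):
            SolverConfig(alpha=0.0)
        with pytest.raises(DomainError):
            SolverConfig(gamma=1.7)
        with pytest.raises(DomainError):
            SolverConfig(lambda_d=-0.1)
        with pytest.raises(DomainError):
            SolverConfig(init_scheme="zeros")
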