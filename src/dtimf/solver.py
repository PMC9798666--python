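"""Alternating-direction solver for constrained dual graph-regularized NMF.

The model completes a binary interaction matrix Z by a low-rank non-negative
factorization X Y^T whose row factors are smooth on a drug similarity graph
and whose column factors are smooth on a target similarity graph, subject to
a *hard* consistency constraint: the prediction matrix M must agree with Z
exactly on the set Omega of known interactions.

The optimization problem, after splitting X = U, Y^T = V to isolate the
non-negativity constraints, is

    min_{X,Y,M,U,V}  1/2 ||M - X Y^T||_F^2
                     + lambda_d Tr(X^T L_d X) + lambda_t Tr(Y^T L_t Y)
    s.t.  X = U,  Y^T = V,  U >= 0,  V >= 0,  P_Omega(Z - M) = 0,

with L_d, L_t the normalized graph Laplacians. It is solved by block
minimization of the augmented Lagrangian with multiplier (dual ascent)
steps: each sweep updates X, Y, M, U, V in closed form and then the
multipliers Lambda, Pi. The X and Y solves are prox-linearized in the
Laplacian term (the term is evaluated at the previous iterate), which keeps
each update a single k x k symmetric positive-definite linear solve.

The prediction matrix is M: it equals 1 on Omega by construction at every
iterate and equals X Y^T elsewhere; off-Omega entries are scores, not
probabilities, and may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import DomainError, NumericalError

__all__ = ["SolverConfig", "SolverState", "project_omega", "project_nonneg",
           "objective", "augmented_lagrangian", "update_X", "update_Y",
           "update_M", "update_U", "update_V", "update_multipliers", "solve"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

INIT_SCHEMES = ("uniform-random", "svd-based")


@dataclass(frozen=True)
class SolverConfig:
    """Hyperparameters of the alternating-direction solver.

    Parameters
    ----------
    k:
        Latent rank; clamped to min(n, m) with a warning if larger.
    lambda_d, lambda_t:
        Graph regularization weights for the drug and target Laplacian
        smoothness terms. Zero switches the corresponding term off. Because
        the Laplacian term is prox-linearized, the iteration is only stable
        when lambda_d * ||L_d|| stays well below alpha and
        lambda_t * ||L_t|| well below beta whenever latent columns die out
        (rank larger than the effective rank); with ||L|| <= 2 and the
        default alpha = 0.5, beta = 0.01, the default 1e-3 keeps a safe
        margin on both sides.
    alpha, beta:
        Positive penalty parameters of the splitting constraints X = U and
        Y^T = V.
    gamma:
        Multiplier step length in (0, (1+sqrt(5))/2]; the default 1.618 is
        the classical over-relaxed choice.
    epsilon:
        Convergence tolerance on the relative Frobenius change of M.
    max_iter:
        Iteration cap; hitting it flags non-convergence without raising.
    p:
        Neighbor count forwarded to graph construction.
    seed:
        Seed for the factor initialization.
    init_scheme:
        "uniform-random" (scale-matched uniform start) or "svd-based"
        (absolute values of the truncated SVD factors of Z).
    """

    k: int = 50
    lambda_d: float = 0.001
    lambda_t: float = 0.001
    alpha: float = 0.5
    beta: float = 0.01
    gamma: float = 1.618
    epsilon: float = 1e-6
    max_iter: int = 500
    p: int = 5
    seed: int = 0
    init_scheme: str = "uniform-random"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DomainError("k must be at least 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise DomainError("alpha and beta must be positive")
        if not 0.0 < self.gamma <= _GOLDEN + 1e-12:
            raise DomainError("gamma must lie in (0, (1+sqrt(5))/2]")
        if self.epsilon <= 0:
            raise DomainError("epsilon must be positive")
        if self.lambda_d < 0 or self.lambda_t < 0:
            raise DomainError("regularization weights must be non-negative")
        if self.init_scheme not in INIT_SCHEMES:
            raise DomainError(f"init_scheme must be one of {INIT_SCHEMES}")


@dataclass
class SolverState:
    """Iterates of the solver.

    ``U`` and ``V`` are the non-negative copies of ``X`` and ``Y^T`` — they
    are the factors to report. ``M`` is the working prediction matrix.
    """

    X: np.ndarray
    Y: np.ndarray
    M: np.ndarray
    U: np.ndarray
    V: np.ndarray
    Lambda: np.ndarray
    Pi: np.ndarray
    iteration: int = 0
    rel_change: float = np.inf
    objective: float = np.nan
    converged: bool = False


def _omega_mask(shape, omega) -> np.ndarray:
    if isinstance(omega, np.ndarray) and omega.dtype == bool:
        if omega.shape != tuple(shape):
            raise DomainError("omega mask shape mismatch")
        return omega
    mask = np.zeros(shape, dtype=bool)
    if len(omega):
        idx = np.array(sorted(omega))
        mask[idx[:, 0], idx[:, 1]] = True
    return mask


def project_omega(A: np.ndarray, Z: np.ndarray, omega) -> np.ndarray:
    """P_Omega: copy of ``A`` with entries outside ``omega`` zeroed.

    ``omega`` may be a set of (i, j) pairs or a boolean mask; ``Z`` fixes
    the expected shape.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != np.shape(Z):
        raise DomainError(f"shape mismatch: {A.shape} vs {np.shape(Z)}")
    mask = _omega_mask(A.shape, omega)
    out = np.zeros_like(A)
    out[mask] = A[mask]
    return out


def project_nonneg(A: np.ndarray) -> np.ndarray:
    """P_+: elementwise maximum with zero."""
    return np.maximum(np.asarray(A, dtype=float), 0.0)


def objective(X, Y, M, L_norm_d, L_norm_t, lambda_d, lambda_t) -> float:
    """1/2 ||M - X Y^T||_F^2 + lambda_d Tr(X^T L_d X) + lambda_t Tr(Y^T L_t Y)."""
    resid = M - X @ Y.T
    val = 0.5 * float(np.sum(resid * resid))
    if lambda_d:
        val += lambda_d * float(np.trace(X.T @ L_norm_d @ X))
    if lambda_t:
        val += lambda_t * float(np.trace(Y.T @ L_norm_t @ Y))
    return val


def augmented_lagrangian(state: SolverState, config: SolverConfig,
                         L_norm_d, L_norm_t) -> float:
    """Objective plus multiplier terms and quadratic split penalties."""
    X, Y = state.X, state.Y
    dX = X - state.U
    dY = Y.T - state.V
    val = objective(X, Y, state.M, L_norm_d, L_norm_t,
                    config.lambda_d, config.lambda_t)
    val += float(np.sum(state.Lambda * dX)) + float(np.sum(state.Pi * dY))
    val += 0.5 * config.alpha * float(np.sum(dX * dX))
    val += 0.5 * config.beta * float(np.sum(dY * dY))
    return val


def _spd_right_solve(B: np.ndarray, G: np.ndarray, block: str,
                     iteration: int) -> np.ndarray:
    """Solve A G = B for A with G symmetric positive definite (k x k)."""
    try:
        c = cho_factor(G, lower=True)
    except np.linalg.LinAlgError as exc:
        # G = F^T F + c I is SPD in exact arithmetic; failure means the
        # iterates overflowed (divergence), not a modelling error
        raise NumericalError(
            f"system matrix for block {block} lost positive definiteness "
            f"at iteration {iteration} (diverging iterates)",
            block=block, iteration=iteration) from exc
    return cho_solve(c, B.T).T


def update_X(state: SolverState, config: SolverConfig, L_norm_d) -> np.ndarray:
    """Closed-form X block: solve X (Y^T Y + alpha I) = RHS.

    The Laplacian smoothness term enters through the previous iterate
    (prox-linearized), so the update is a single SPD solve; no explicit
    inverse is formed.
    """
    Y = state.Y
    k = Y.shape[1]
    rhs = state.M @ Y + config.alpha * state.U - state.Lambda
    if config.lambda_d:
        rhs = rhs - config.lambda_d * (L_norm_d @ state.X)
    X_next = _spd_right_solve(rhs, Y.T @ Y + config.alpha * np.eye(k),
                              "X", state.iteration)
    _check_finite(X_next, "X", state.iteration)
    return X_next


def update_Y(state: SolverState, config: SolverConfig, L_norm_t) -> np.ndarray:
    """Closed-form Y block, using the X just updated in this sweep."""
    X = state.X
    k = X.shape[1]
    rhs = state.M.T @ X + config.beta * state.V.T - state.Pi.T
    if config.lambda_t:
        rhs = rhs - config.lambda_t * (L_norm_t @ state.Y)
    Y_next = _spd_right_solve(rhs, X.T @ X + config.beta * np.eye(k),
                              "Y", state.iteration)
    _check_finite(Y_next, "Y", state.iteration)
    return Y_next


def update_M(X_next, Y_next, Z, omega) -> np.ndarray:
    """Prediction matrix: Z on Omega (exactly), X Y^T elsewhere.

    Because every feasible iterate satisfies P_Omega(M) = P_Omega(Z), the
    constrained minimization of the fit term reduces to overwriting the
    Omega entries of X Y^T with those of Z, which makes
    P_Omega(Z - M) = 0 hold bitwise from the first sweep.
    """
    mask = _omega_mask(np.shape(Z), omega)
    M_next = X_next @ Y_next.T
    M_next[mask] = np.asarray(Z, dtype=float)[mask]
    return M_next


def update_U(X_next, Lambda, alpha: float) -> np.ndarray:
    """Non-negative copy of X: P_+(X + Lambda / alpha)."""
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    return project_nonneg(X_next + Lambda / alpha)


def update_V(Y_next, Pi, beta: float) -> np.ndarray:
    """Non-negative copy of Y^T: P_+(Y^T + Pi / beta)."""
    if beta <= 0:
        raise DomainError("beta must be positive")
    return project_nonneg(Y_next.T + Pi / beta)


def update_multipliers(state: SolverState, config: SolverConfig):
    """Dual ascent: Lambda += gamma*alpha*(X - U); Pi += gamma*beta*(Y^T - V)."""
    Lambda_next = state.Lambda + config.gamma * config.alpha * (state.X - state.U)
    Pi_next = state.Pi + config.gamma * config.beta * (state.Y.T - state.V)
    return Lambda_next, Pi_next


def _check_finite(A: np.ndarray, block: str, iteration: int) -> None:
    if not np.isfinite(A).all():
        raise NumericalError(
            f"non-finite values in block {block} at iteration {iteration}",
            block=block, iteration=iteration)


def _initial_state(Z: np.ndarray, mask: np.ndarray, k: int,
                   config: SolverConfig) -> SolverState:
    n, m = Z.shape
    rng = np.random.default_rng(config.seed)
    if config.init_scheme == "svd-based":
        Uz, s, Vtz = np.linalg.svd(Z, full_matrices=False)
        X0 = np.abs(Uz[:, :k] * np.sqrt(s[:k]))
        Y0 = np.abs(Vtz[:k].T * np.sqrt(s[:k]))
        # break exact zeros so the first sweeps are not rank-deficient
        X0 += 1e-8 * rng.uniform(size=X0.shape)
        Y0 += 1e-8 * rng.uniform(size=Y0.shape)
    else:
        scale = np.sqrt(max(float(Z.mean()), 1e-4) / k)
        X0 = rng.uniform(0.0, scale, size=(n, k))
        Y0 = rng.uniform(0.0, scale, size=(m, k))
    M0 = Z.astype(float).copy()
    return SolverState(X=X0, Y=Y0, M=M0, U=X0.copy(), V=Y0.T.copy(),
                       Lambda=np.zeros((n, k)), Pi=np.zeros((k, m)))


def solve(Z, omega, L_norm_d, L_norm_t, config: SolverConfig,
          callback=None):
    """Run the alternating-direction iteration until M stabilizes.

    Parameters
    ----------
    Z:
        Binary (n, m) interaction matrix (training copy; masked rows or
        columns are simply zero).
    omega:
        Known-interaction index set — a set of (i, j) pairs or a boolean
        mask. Must index the 1-entries of ``Z``.
    L_norm_d, L_norm_t:
        Normalized graph Laplacians for drugs (n x n) and targets (m x m).
    config:
        Solver hyperparameters. ``config.k`` is clamped to min(n, m) with a
        warning when it exceeds it.
    callback:
        Optional callable invoked with the state after every full sweep.

    Returns
    -------
    (state, trace):
        Final :class:`SolverState` (``state.M`` is the prediction matrix;
        ``state.converged`` flags whether the tolerance was reached) and a
        DataFrame with per-iteration objective, relative change of M, and
        primal residuals ``||X - U||_F``, ``||Y^T - V||_F``.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    mask = _omega_mask(Z.shape, omega)
    if not (Z[mask] == 1.0).all():
        raise DomainError("omega must index 1-entries of Z")
    k = config.k
    if k > min(n, m):
        warnings.warn(f"rank k={k} exceeds min(n, m)={min(n, m)}; clamping",
                      stacklevel=2)
        k = min(n, m)

    state = _initial_state(Z, mask, k, config)
    rows = []
    for it in range(1, config.max_iter + 1):
        state.iteration = it
        M_prev = state.M
        state.X = update_X(state, config, L_norm_d)
        state.Y = update_Y(state, config, L_norm_t)
        state.M = update_M(state.X, state.Y, Z, mask)
        _check_finite(state.M, "M", it)
        state.U = update_U(state.X, state.Lambda, config.alpha)
        state.V = update_V(state.Y, state.Pi, config.beta)
        state.Lambda, state.Pi = update_multipliers(state, config)
        _check_finite(state.Lambda, "Lambda", it)
        _check_finite(state.Pi, "Pi", it)

        state.rel_change = float(
            np.linalg.norm(state.M - M_prev) / max(np.linalg.norm(M_prev), 1.0))
        state.objective = objective(state.X, state.Y, state.M,
                                    L_norm_d, L_norm_t,
                                    config.lambda_d, config.lambda_t)
        res_x = float(np.linalg.norm(state.X - state.U))
        res_y = float(np.linalg.norm(state.Y.T - state.V))
        rows.append((it, state.objective, state.rel_change, res_x, res_y))
        if callback is not None:
            callback(state)
        if state.rel_change < config.epsilon:
            state.converged = True
            break

    trace = pd.DataFrame(rows, columns=["iteration", "objective",
                                        "rel_change", "res_primal_x",
                                        "res_primal_y"])
    return state, trace
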