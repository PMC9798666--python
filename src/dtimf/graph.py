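"""p-nearest-neighbor graph sparsification and normalized Laplacians.

A dense similarity matrix is turned into a sparse weighted neighbor graph:
an edge gets weight 1 when each endpoint is among the other's p most similar
items, 0 when neither is, and 0.5 when exactly one is. The sparsified
similarity is the elementwise product of these weights with the original
similarities; its normalized Laplacian D^{-1/2} (D - S_hat) D^{-1/2} is the
smoothness operator used by the solver's graph regularization terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["GraphOperators", "pnn_weights", "sparsify",
           "normalized_laplacian", "build_graph_operators"]


@dataclass(frozen=True)
class GraphOperators:
    """The graph operators derived from one similarity matrix.

    ``N`` holds neighbor weights in {0, 0.5, 1}; ``S_hat = N * S``
    elementwise; ``D`` is the diagonal degree matrix of ``S_hat``; ``L`` the
    combinatorial Laplacian ``D - S_hat``; ``L_norm`` its symmetric
    normalization, with zero-degree vertices handled by the pseudo-inverse
    of ``D^{1/2}`` (their ``L_norm`` diagonal entry is 0).
    """

    N: np.ndarray
    S_hat: np.ndarray
    D: np.ndarray
    L: np.ndarray
    L_norm: np.ndarray
    p: int


def pnn_weights(S: np.ndarray, p: int) -> np.ndarray:
    """Mutual/one-sided p-nearest-neighbor weight matrix.

    ``N[i, j]`` is 1 when j is among the p most similar items to i *and*
    vice versa, 0 when neither membership holds, and 0.5 otherwise. The
    neighbor set of i excludes i itself; ties in similarity are broken by
    ascending index so the graph is deterministic. The diagonal is 0.
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    if S.shape != (d, d):
        raise DomainError("similarity matrix must be square")
    if not 1 <= p <= d - 1:
        raise DomainError(f"p must be in [1, {d - 1}], got {p}")
    member = np.zeros((d, d), dtype=bool)
    for i in range(d):
        # stable sort on -S[i] -> ties resolved toward smaller index
        order = np.argsort(-S[i], kind="stable")
        order = order[order != i][:p]
        member[i, order] = True
    both = member & member.T
    either = member | member.T
    N = np.where(both, 1.0, np.where(either, 0.5, 0.0))
    np.fill_diagonal(N, 0.0)
    return N


def sparsify(S: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Elementwise product of similarities with neighbor weights."""
    S = np.asarray(S, dtype=float)
    N = np.asarray(N, dtype=float)
    if S.shape != N.shape:
        raise DomainError(f"shape mismatch: S {S.shape} vs N {N.shape}")
    return N * S


def normalized_laplacian(S_hat: np.ndarray):
    """Degree matrix, combinatorial Laplacian and its symmetric normalization.

    Returns ``(D, L, L_norm)`` with ``L = D - S_hat`` and
    ``L_norm = D^{-1/2} L D^{-1/2}``. Rows with zero degree (isolated
    vertices) use the pseudo-inverse convention: their scaling factor is 0,
    leaving zero rows/columns in ``L_norm``.
    """
    S_hat = np.asarray(S_hat, dtype=float)
    if S_hat.min() < 0:
        raise DomainError("sparsified similarity must be non-negative")
    deg = S_hat.sum(axis=1)
    D = np.diag(deg)
    L = D - S_hat
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)),
                            0.0)
    L_norm = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    L_norm = 0.5 * (L_norm + L_norm.T)
    return D, L, L_norm


def build_graph_operators(S: np.ndarray, p: int) -> GraphOperators:
    """Construct all graph operators for one similarity matrix."""
    N = pnn_weights(S, p)
    S_hat = sparsify(S, N)
    D, L, L_norm = normalized_laplacian(S_hat)
    return GraphOperators(N=N, S_hat=S_hat, D=D, L=L, L_norm=L_norm, p=p)
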