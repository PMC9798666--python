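"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over definitions, deliberately
sharing no code path with the package, so agreement is meaningful.
"""

import numpy as np


def pnn_oracle(S, p):
    """Neighbor weights by explicit enumeration of each p-most-similar set."""
    d = S.shape[0]
    neighbor_sets = []
    for i in range(d):
        # sort candidates by (descending similarity, ascending index)
        candidates = sorted((j for j in range(d) if j != i),
                            key=lambda j: (-S[i, j], j))
        neighbor_sets.append(set(candidates[:p]))
    N = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            in_i = j in neighbor_sets[i]
            in_j = i in neighbor_sets[j]
            if in_i and in_j:
                N[i, j] = 1.0
            elif in_i or in_j:
                N[i, j] = 0.5
    return N


def objective_oracle(X, Y, M, Ld, Lt, lam_d, lam_t):
    """Scalar-loop evaluation of the regularized factorization objective."""
    n, m = M.shape
    k = X.shape[1]
    fit = 0.0
    for i in range(n):
        for j in range(m):
            pred = sum(X[i, r] * Y[j, r] for r in range(k))
            fit += (M[i, j] - pred) ** 2
    tr_d = sum(X[i, r] * Ld[i, l] * X[l, r]
               for r in range(k) for i in range(n) for l in range(n))
    tr_t = sum(Y[j, r] * Lt[j, q] * Y[q, r]
               for r in range(k) for j in range(m) for q in range(m))
    return 0.5 * fit + lam_d * tr_d + lam_t * tr_t


def auglag_oracle(X, Y, M, U, V, Lam, Pi, Ld, Lt, lam_d, lam_t, alpha, beta):
    """Scalar-loop evaluation of the augmented Lagrangian."""
    val = objective_oracle(X, Y, M, Ld, Lt, lam_d, lam_t)
    n, k = X.shape
    m = Y.shape[0]
    for i in range(n):
        for r in range(k):
            diff = X[i, r] - U[i, r]
            val += Lam[i, r] * diff + 0.5 * alpha * diff ** 2
    for r in range(k):
        for j in range(m):
            diff = Y[j, r] - V[r, j]
            val += Pi[r, j] * diff + 0.5 * beta * diff ** 2
    return val


def auc_oracle(labels, scores):
    """Mann-Whitney pairwise comparison with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_oracle(labels, scores):
    """Step-wise (non-interpolated) area under the precision-recall curve.

    AP = sum over descending-score prefixes where a positive enters of
    (recall step) * (precision at that prefix); ties handled by grouping
    equal scores into one threshold step.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(scores), reverse=True):
        selected = scores >= threshold
        tp = labels[selected].sum()
        precision = tp / selected.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
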