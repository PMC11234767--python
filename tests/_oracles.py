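"""Independent brute-force implementations used only as test oracles.

These deliberately avoid the package's code paths: explicit inverses,
elementwise loops, eigendecompositions instead of SVD routines, and normal
equations instead of lstsq, so that agreement with the package is a real
cross-check rather than a tautology.
"""

import numpy as np


def blup_conditional_mean(y1, W11, W21, s2g, s2e):
    """E[g2 | y1] and E[g1 | y1] from the joint multivariate normal."""
    n1 = len(y1)
    V = np.empty((n1, n1))
    for i in range(n1):
        for j in range(n1):
            V[i, j] = s2g * W11[i, j] + (s2e if i == j else 0.0)
    Vinv = np.linalg.inv(V)
    g1 = s2g * (W11 @ (Vinv @ y1))
    g2 = s2g * (W21 @ (Vinv @ y1))
    return g1, g2


def mme_solution(y1, W11, s2g, s2e):
    """Henderson mixed-model-equation path for the reference breeding values."""
    n1 = len(y1)
    lhs = np.eye(n1) / s2e + np.linalg.inv(W11) / s2g
    return np.linalg.solve(lhs, y1 / s2e)


def single_step_H(A, G, g_idx, u_idx, beta):
    """Block-formula single-step matrix assembled independently."""
    Agg = A[np.ix_(g_idx, g_idx)]
    Agu = A[np.ix_(g_idx, u_idx)]
    Aug = A[np.ix_(u_idx, g_idx)]
    Auu = A[np.ix_(u_idx, u_idx)]
    Agg_inv = np.linalg.inv(Agg)
    Gs = beta * G + (1.0 - beta) * Agg
    n = A.shape[0]
    H = np.zeros((n, n))
    H[np.ix_(g_idx, g_idx)] = Gs
    if len(u_idx):
        H[np.ix_(u_idx, g_idx)] = Aug @ Agg_inv @ Gs
        H[np.ix_(g_idx, u_idx)] = (Aug @ Agg_inv @ Gs).T
        H[np.ix_(u_idx, u_idx)] = Auu + Aug @ Agg_inv @ (Gs - Agg) @ Agg_inv @ Agu
    return H


def expected_R_gblup_dense(W11, W12, W21, s2g, s2e, h2_hat):
    """Eq.-by-eq evaluation of the mean GBLUP reliability with explicit inverses."""
    n1 = W11.shape[0]
    n2 = W21.shape[0]
    W11_inv = np.linalg.inv(W11)
    lhs = np.eye(n1) / s2e + W11_inv / s2g
    mid = W11 - np.linalg.inv(lhs * s2g)
    bracket = W21 @ W11_inv @ mid @ W11_inv @ W12
    total = 0.0
    for i in range(n2):
        d = bracket[i, i]
        total += np.sqrt(max(d, 0.0))
    return np.sqrt(h2_hat) / n2 * total


def r_gblup_dense(W11, W21, W12):
    bracket = W21 @ np.linalg.inv(W11) @ W12
    vals = [np.sqrt(max(bracket[i, i], 0.0)) for i in range(W21.shape[0])]
    return float(np.mean(vals))


def _svd_by_eigh(M):
    """Singular values and right vectors via the eigendecomposition of MM'."""
    n, m = M.shape
    ev, U = np.linalg.eigh(M @ M.T)
    order = np.argsort(ev)[::-1]
    ev = np.clip(ev[order], 0.0, None)
    U = U[:, order]
    d = np.sqrt(ev)
    V = np.zeros((m, n))
    for k in range(n):
        if d[k] > 1e-12 * max(d[0], 1e-300):
            V[:, k] = M.T @ U[:, k] / d[k]
    return U, d, V


def igc_svd_bruteforce(M1, M2):
    """IGC from genomic data with loops and eigendecompositions only."""
    n1, m = M1.shape
    n2 = M2.shape[0]
    _, d1, V1 = _svd_by_eigh(M1)
    _, d2, V2 = _svd_by_eigh(M2)
    T = np.zeros((n2, n1))
    for i in range(n2):
        for j in range(n1):
            acc = 0.0
            for t in range(m):
                acc += V2[t, i] * V1[t, j]
            T[i, j] = np.sqrt(n2 / n1) * acc * d1[j]
    _, dT, _ = _svd_by_eigh(T)
    eps = np.finfo(float).eps

    def rank(d, shape):
        if d[0] == 0.0:
            return 0
        tol = max(shape) * eps * d[0]
        return int(np.sum(d > tol))

    k = min(rank(d1, M1.shape), rank(d2, M2.shape), len(dT))
    x, y = d2[:k], dT[:k]
    # normal equations for y = a + b x + c x^2
    X = np.zeros((3, 3))
    b = np.zeros(3)
    for xi, yi in zip(x, y):
        row = np.array([1.0, xi, xi * xi])
        X += np.outer(row, row)
        b += row * yi
    coef = np.linalg.solve(X, b)
    return float(np.clip(coef.sum(), 0.0, 1.0)), tuple(coef)


def quad_fit_normal_equations(x, y):
    X = np.zeros((3, 3))
    b = np.zeros(3)
    for xi, yi in zip(x, y):
        row = np.array([1.0, xi, xi * xi])
        X += np.outer(row, row)
        b += row * yi
    return np.linalg.solve(X, b)


def tabular_A_full(order, parents):
    """Plain scalar-loop tabular method; ``parents[id] = (sire|None, dam|None)``."""
    pos = {s: i for i, s in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, s in enumerate(order):
        si, di = parents[s]
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * A[pos[si], j]
            if di is not None:
                val += 0.5 * A[pos[di], j]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0
        if si is not None and di is not None:
            A[i, i] += 0.5 * A[pos[si], pos[di]]
    return A
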