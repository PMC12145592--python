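"""Independent reference implementations used only to verify the package.

These deliberately favor literal, loop-heavy formulations over the vectorized
algorithms in the package so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def nipals_pls(X, Y, n_components, tol=1e-12, max_iter=1000):
    """Classical NIPALS PLS2 with X and Y deflation.

    Returns dict with centered means, weights W, loadings P, Q, scores T and
    the coefficient stack B[a] = W_a (P_a' W_a)^-1 Q_a' for a = 1..A.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xa, Ya = X - x_mean, Y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xa.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                break
            w_new /= nw
            t = Xa @ w_new
            q = Ya.T @ t / (t @ t)
            u_new = Ya @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xa @ w
        tt = t @ t
        p_a = Xa.T @ t / tt
        q_a = Ya.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, q_a)
    B = []
    for a in range(1, n_components + 1):
        Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
        B.append(Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T))
    return {"x_mean": x_mean, "y_mean": y_mean, "W": W, "P": P, "Q": Q, "T": T, "B": B}


def nipals_predict(fit, X_new, a):
    X_new = np.asarray(X_new, dtype=float)
    return (X_new - fit["x_mean"]) @ fit["B"][a - 1] + fit["y_mean"]


def brute_force_loo_rmsecv(X, Y, a_max):
    """Literal refit-per-fold LOO using the NIPALS oracle."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape[0], Y.shape[1]
    preds = np.empty((n, a_max, m))
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        fit = nipals_pls(X[rest], Y[rest], a_max)
        for a in range(1, a_max + 1):
            preds[i, a - 1] = nipals_predict(fit, X[i][None, :], a)[0]
    rmsecv = np.empty((m, a_max))
    for j in range(m):
        for a in range(a_max):
            rmsecv[j, a] = np.sqrt(np.mean((preds[:, a, j] - Y[:, j]) ** 2))
    return rmsecv


def brute_force_kennard_stone(points, k):
    """Greedy max-min selection with explicit loops and lowest-index ties."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)

    def dist(i, j):
        return float(np.sqrt(np.sum((pts[i] - pts[j]) ** 2)))

    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(i, j)
            if d > best[0]:
                best = (d, (i, j))
    selected = list(best[1])
    while len(selected) < k:
        best_idx, best_min = None, -1.0
        for c in range(n):
            if c in selected:
                continue
            dmin = min(dist(c, s) for s in selected)
            if dmin > best_min:
                best_idx, best_min = c, dmin
        selected.append(best_idx)
    return selected
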