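"""Geomin rotation by gradient projection.

The geomin criterion ``q(L) = sum_i (prod_j (l_ij^2 + eps))^(1/p)`` rewards
rows with at least one near-zero entry, giving interpretable oblique simple
structure.  Minimization follows the gradient-projection algorithm of
Jennrich (oblique and orthogonal variants), with multiple random orthogonal
starts because the criterion is multimodal.

After rotation, factors are ordered by descending sum of squared loadings
and signed so each factor's largest-magnitude item loads positively, making
the reported solution deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["geomin_criterion", "geomin_rotate"]


def geomin_criterion(L: np.ndarray, epsilon: float = 0.01):
    """Geomin criterion value and gradient with respect to the loadings."""
    L = np.asarray(L, dtype=float)
    p = L.shape[1]
    L2 = L**2 + epsilon
    pro = np.exp(np.sum(np.log(L2), axis=1) / p)      # row geometric means
    f = float(np.sum(pro))
    G = (2.0 / p) * (L / L2) * pro[:, None]
    return f, G


def _normalize_solution(L, Phi):
    order = np.argsort(-np.sum(L**2, axis=0))
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


def _gpa_oblique(A, T0, epsilon, max_iter=500, tol=1e-6):
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = geomin_criterion(L, epsilon)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)   # project out column-scale direction
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gqt = geomin_criterion(Lt, epsilon)
            if ft < f - 0.5 * s**2 * al * 1e-4:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Xi, Lt, ft, Gqt
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f


def _gpa_orthogonal(A, T0, epsilon, max_iter=500, tol=1e-6):
    T = T0.copy()
    L = A @ T
    f, Gq = geomin_criterion(L, epsilon)
    G = A.T @ Gq
    al = 1.0
    for _ in range(max_iter):
        M = T.T @ G
        Gp = G - T @ (M + M.T) / 2
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            U, _, Vt = np.linalg.svd(X)
            X = U[:, : T.shape[1]] @ Vt
            Lt = A @ X
            ft, Gqt = geomin_criterion(Lt, epsilon)
            if ft < f - 0.5 * s**2 * al * 1e-4:
                break
            al /= 2.0
        T, L, f, Gq = X, Lt, ft, Gqt
        G = A.T @ Gq
    return L, np.eye(T.shape[1]), f


def geomin_rotate(loadings: np.ndarray, epsilon: float = 0.01, oblique: bool = True,
                  n_starts: int = 30, seed: int = 0):
    """Geomin-rotate a loading matrix.

    Returns ``(rotated_loadings, factor_correlation)``; the factor
    correlation is the identity for orthogonal rotation.  The best of
    ``n_starts`` random orthogonal starts (by criterion value, ties to the
    first start) is kept.
    """
    A = np.atleast_2d(np.asarray(loadings, dtype=float))
    M, p = A.shape
    if p < 1 or epsilon <= 0:
        raise ValueError("need p >= 1 factors and epsilon > 0")
    if p == 1:
        L, Phi = _normalize_solution(A.copy(), np.eye(1))
        return L, Phi
    if np.linalg.matrix_rank(A) < p:
        raise ValueError("loading matrix is rank deficient; rotation undefined")
    rng = np.random.default_rng(seed)
    rotator = _gpa_oblique if oblique else _gpa_orthogonal
    best = None
    for k in range(n_starts):
        if k == 0:
            T0 = np.eye(p)
        else:
            Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
            T0 = Q
        L, Phi, f = rotator(A, T0, epsilon)
        if best is None or f < best[2] - 1e-12:
            best = (L, Phi, f)
    L, Phi, _ = best
    return _normalize_solution(L, Phi)
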