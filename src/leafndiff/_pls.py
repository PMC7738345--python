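"""Lean single-response PLS (SIMPLS) and cross-validation helpers.

The interval- and variable-screening loops evaluate hundreds of thousands of
small PLS fits; this module provides a minimal vectorized PLS1 whose
predictions coincide with the standard NIPALS implementation for a single
response (they span the same Krylov subspace), plus seeded K-fold RMSECV
utilities for PLS and ordinary least squares.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simpls_coefficients", "pls_cv_rmse", "ols_cv_rmse", "kfold_indices"]


def simpls_coefficients(X: np.ndarray, y: np.ndarray,
                        n_components: int) -> tuple[np.ndarray, np.ndarray, float]:
    """SIMPLS regression vector for one response.

    Returns ``(beta, x_mean, y_mean)`` with predictions
    ``(Xnew - x_mean) @ beta + y_mean``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    k = min(n_components, p, n - 1)
    if k < 1:
        raise ValueError("need at least one latent component")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    R = np.zeros((p, k))
    V = np.zeros((p, k))
    q = np.zeros(k)
    for a in range(k):
        r = s.copy()
        t = Xc @ r
        normt = np.linalg.norm(t)
        if normt <= 1e-12 * max(1.0, np.linalg.norm(yc)):
            k = a  # remaining components carry nothing
            break
        t /= normt
        r /= normt
        pl = Xc.T @ t
        q[a] = float(yc @ t)
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            k = a
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
    beta = R[:, :k] @ q[:k]
    return beta, x_mean, y_mean


def simpls_from_gram(G: np.ndarray, s0: np.ndarray,
                     n_components: int) -> np.ndarray:
    """SIMPLS regression vector from centered cross-products.

    ``G = Xc.T @ Xc`` and ``s0 = Xc.T @ yc`` fully determine the PLS1
    solution; this lets interval screens slice precomputed Gram matrices
    instead of re-centering raw data for every candidate subset.  Returns
    ``beta`` on centered data (same vector as :func:`simpls_coefficients`).
    """
    p = G.shape[0]
    k = min(n_components, p)
    s = s0.copy()
    R = np.zeros((p, k))
    V = np.zeros((p, k))
    q = np.zeros(k)
    ref = np.linalg.norm(s0)
    for a in range(k):
        r = s.copy()
        Gr = G @ r
        tt = float(r @ Gr)
        if tt <= (1e-12 * max(1.0, ref)) ** 2:
            k = a
            break
        normt = np.sqrt(tt)
        r /= normt
        pl = Gr / normt
        q[a] = float(s0 @ r)
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            k = a
            break
        v /= nv
        s = s - v * (v @ s)
        R[:, a] = r
        V[:, a] = v
    return R[:, :k] @ q[:k]


def kfold_indices(n: int, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffled K-fold partition of range(n)."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError(f"{folds} folds exceed {n} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::folds] for i in range(folds)]


def _cv_rmse(X, y, fold_idx, fit_predict) -> float:
    n = len(y)
    sq = 0.0
    for test in fold_idx:
        train = np.setdiff1d(np.arange(n), test, assume_unique=False)
        pred = fit_predict(X[train], y[train], X[test])
        sq += float(np.sum((y[test] - pred) ** 2))
    return float(np.sqrt(sq / n))


def pls_cv_rmse(X: np.ndarray, y: np.ndarray, n_components: int = 5,
                folds: int = 10, seed: int = 0,
                fold_idx: list[np.ndarray] | None = None) -> float:
    """K-fold RMSECV of a PLS1 model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if fold_idx is None:
        fold_idx = kfold_indices(len(y), folds, seed)

    def fit_predict(Xtr, ytr, Xte):
        beta, xm, ym = simpls_coefficients(Xtr, ytr, n_components)
        return (Xte - xm) @ beta + ym

    return _cv_rmse(X, y, fold_idx, fit_predict)


def ols_cv_rmse(X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0,
                fold_idx: list[np.ndarray] | None = None) -> float:
    """K-fold RMSECV of ordinary least squares with intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if fold_idx is None:
        fold_idx = kfold_indices(len(y), folds, seed)

    def fit_predict(Xtr, ytr, Xte):
        A = np.column_stack([Xtr, np.ones(len(ytr))])
        coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        return np.column_stack([Xte, np.ones(len(Xte))]) @ coef

    return _cv_rmse(X, y, fold_idx, fit_predict)
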