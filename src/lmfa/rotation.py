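"""Oblique factor rotation by gradient projection.

Implements the gradient-projection algorithm (GPA) for oblique rotation with
the quartimin criterion (oblimin with gamma = 0), the conventional default
for obtaining a simple structure with correlated factors.  Given an
identified loading matrix A (factor covariance fixed to the identity), an
oblique rotation matrix T with unit-length columns produces the pattern
matrix L = A (T')^{-1} and factor correlation matrix Phi = T'T, leaving the
common covariance A A' = L Phi L' unchanged.

The criterion surface is multimodal, so the search is restarted from several
random rotation matrices and the best (lowest criterion) converged solution
is kept.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quartimin_criterion", "gpa_oblique", "rotate_pattern", "normalize_pattern"]


class RotationError(RuntimeError):
    """Raised when the rotation search fails to converge from every start."""


def quartimin_criterion(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin value and its gradient with respect to the pattern L.

    f(L) = sum_j sum_{p != q} L_jp^2 L_jq^2 / 4; small values mean each item
    loads on few factors.
    """
    L2 = L**2
    F = L.shape[1]
    N = np.ones((F, F)) - np.eye(F)
    M = L2 @ N
    f = float(np.sum(L2 * M)) / 4.0
    grad = L * M
    return f, grad


def _gpa_oblique_once(
    A: np.ndarray, T0: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One GPA run from rotation start T0; returns (pattern, Phi, f, converged)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = quartimin_criterion(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        # project the gradient onto the manifold of unit-length columns
        Gp = G - T * np.sum(T * G, axis=0, keepdims=True)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            nrm = np.sqrt(np.sum(X**2, axis=0))
            Tt = X / nrm
            Ti = np.linalg.inv(Tt)
            Lt = A @ Ti.T
            ft, Gq = quartimin_criterion(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f = Tt, Lt, ft
        G = -(L.T @ Gq @ Ti).T
    return L, T.T @ T, f, converged


def gpa_oblique(
    A: np.ndarray,
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Quartimin-rotate an identified loading matrix from multiple starts.

    Returns the pattern matrix and factor correlation matrix of the best
    converged solution.  The first start is the identity rotation; the
    remaining starts are random orthonormal matrices.
    """
    A = np.asarray(A, dtype=float)
    F = A.shape[1]
    if F == 1:
        return A.copy(), np.ones((1, 1))
    # the optimal rotation is invariant to a global rescaling of A, but the
    # quartic criterion (and its gradient) is not: normalize so the
    # gradient tolerance has a consistent meaning across loading scales
    scale = np.sqrt(np.mean(A**2))
    if scale <= 0:
        return A.copy(), np.eye(F)
    An = A / scale
    rng = np.random.default_rng(rng)
    best = None
    for i in range(max(1, n_starts)):
        if i == 0:
            T0 = np.eye(F)
        else:
            T0, _ = np.linalg.qr(rng.standard_normal((F, F)))
        L, Phi, f, ok = _gpa_oblique_once(An, T0, max_iter=max_iter, tol=tol)
        if ok and (best is None or f < best[2]):
            best = (L, Phi, f)
    if best is None:
        raise RotationError("oblique rotation did not converge from any start")
    return best[0] * scale, best[1]


def normalize_pattern(L: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve reflection and permutation indeterminacy of a rotated solution.

    Each factor is reflected so its largest-|loading| item loads positively,
    and factors are ordered by explained common variance (descending sum of
    squared pattern loadings).  Phi is permuted/reflected accordingly.
    """
    L = L.copy()
    Phi = Phi.copy()
    F = L.shape[1]
    signs = np.ones(F)
    for q in range(F):
        j = int(np.argmax(np.abs(L[:, q])))
        if L[j, q] < 0:
            signs[q] = -1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    return L, Phi


def rotate_pattern(
    A: np.ndarray, n_starts: int = 10, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate, then normalize sign/order.  Convenience wrapper over GPA."""
    L, Phi = gpa_oblique(A, n_starts=n_starts, rng=rng)
    return normalize_pattern(L, Phi)
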