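"""Oblique geomin rotation by gradient projection.

The geomin criterion sum_i (prod_k (lambda_ik^2 + eps))^(1/K) rewards rows
with at least one near-zero entry, i.e. simple structure.  With small eps
and three or more factors the criterion is multimodal, so the rotation is
restarted from many random oblique positions and the best converged
solution kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = ["rotate_geomin", "RotationResult", "RotationError", "align_to_target", "congruence"]


class RotationError(RuntimeError):
    """No rotation start converged; carries the best criterion value seen."""

    def __init__(self, message, best_criterion=None):
        super().__init__(message)
        self.best_criterion = best_criterion


@dataclass(frozen=True)
class RotationResult:
    loadings: np.ndarray
    phi: np.ndarray
    criterion: float
    converged: bool
    n_starts: int


def _geomin_value_grad(L: np.ndarray, eps: float):
    K = L.shape[1]
    L2 = L * L + eps
    pro = np.exp(np.sum(np.log(L2), axis=1) / K)  # row geometric means
    f = float(np.sum(pro))
    Gq = (2.0 / K) * (L / L2) * pro[:, None]
    return f, Gq


def _gpf_oblique(A, T, eps, max_iter, tol=1e-6):
    """Gradient projection for oblique rotation (Bernaards & Jennrich)."""
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_value_grad(L, eps)
    G = -(L.T @ Gq @ Ti).T
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp * Gp))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X * X, axis=0))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gqt = _geomin_value_grad(Lt, eps)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, L, f, Gq, Ti = X, Lt, ft, Gqt, Xi
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, f, converged


def rotate_geomin(
    loadings: np.ndarray,
    eps: float = 0.01,
    n_starts: int = 30,
    max_iter: int = 1000,
    seed: int = 0,
    target: np.ndarray | None = None,
):
    """Obliquely rotate an unrotated loading matrix to minimise geomin.

    Returns a :class:`RotationResult` with rotated loadings and factor
    correlations.  When ``target`` is given, the solution's columns are
    permuted and sign-flipped to maximise congruence with it (the implied
    correlation matrix is unaffected by either operation).
    """
    A = np.asarray(loadings, dtype=float)
    K = A.shape[1]
    if K < 2:
        raise ValueError("rotation requires at least two factors")
    rng = np.random.default_rng(seed)
    best = None
    best_any = np.inf
    for start in range(n_starts):
        if start == 0:
            T0 = np.eye(K)
        else:
            T0 = rng.standard_normal((K, K))
            T0 = T0 / np.sqrt(np.sum(T0 * T0, axis=0))
        try:
            L, phi, f, conv = _gpf_oblique(A, T0, eps, max_iter)
        except np.linalg.LinAlgError:
            continue
        best_any = min(best_any, f)
        if conv and (best is None or f < best[2]):
            best = (L, phi, f)
    if best is None:
        raise RotationError(
            f"geomin rotation failed to converge in {n_starts} starts",
            best_criterion=best_any,
        )
    L, phi, f = best
    if target is not None:
        L, phi = align_to_target(L, phi, target)
    return RotationResult(loadings=L, phi=phi, criterion=f, converged=True, n_starts=n_starts)


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient between two loading vectors."""
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def align_to_target(L: np.ndarray, phi: np.ndarray, target: np.ndarray):
    """Permute/sign-flip factors to maximise total |congruence| with target."""
    K = L.shape[1]
    C = np.array([[congruence(L[:, k], target[:, m]) for m in range(K)] for k in range(K)])
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(K)):
        score = sum(abs(C[perm[m], m]) for m in range(K))
        if score > best_score:
            best_score, best_perm = score, perm
    order = list(best_perm)
    signs = np.array([np.sign(C[order[m], m]) or 1.0 for m in range(K)])
    L_out = L[:, order] * signs[None, :]
    phi_out = phi[np.ix_(order, order)] * np.outer(signs, signs)
    return L_out, phi_out
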