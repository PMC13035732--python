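"""Multi-right-hand-side non-negative least squares.

Solves ``min_{Z >= 0} ||A Z - B||_F`` for all columns of ``B`` at once using
block principal pivoting with a shared Gram matrix and grouping of columns
that share an active set — the standard kernel for alternating-NNLS NMF,
where thousands of tiny NNLS problems share one coefficient matrix.
Columns that fail to terminate fall back to ``scipy.optimize.nnls``.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = ["nnls_multi", "NNLSError"]


class NNLSError(RuntimeError):
    """Raised when a column's NNLS solve fails to converge."""

    def __init__(self, column: int, msg: str = ""):
        self.column = column
        super().__init__(f"NNLS failed for column {column}" + (f": {msg}" if msg else ""))


def _solve_passive(AtA: np.ndarray, AtB: np.ndarray, F: np.ndarray, Z: np.ndarray) -> None:
    """Solve the unconstrained normal equations on each column's passive set,
    batching columns with identical passive-set patterns."""
    q, k = Z.shape
    patterns, inverse = np.unique(F, axis=1, return_inverse=True)
    for p in range(patterns.shape[1]):
        f = patterns[:, p]
        cols = np.flatnonzero(inverse == p)
        if not f.any():
            Z[:, cols] = 0.0
            continue
        sub = AtA[np.ix_(f, f)]
        rhs = AtB[np.ix_(f, cols)]
        # rank-deficient passive sets arise routinely on exactly low-rank
        # data; fall back to the min-norm solution instead of warning
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            try:
                sol = scipy.linalg.solve(sub, rhs, assume_a="pos")
            except (scipy.linalg.LinAlgError, scipy.linalg.LinAlgWarning, ValueError):
                sol = np.linalg.lstsq(sub, rhs, rcond=None)[0]
        Z[:, cols] = 0.0
        Z[np.ix_(f, cols)] = sol


def nnls_multi(A, B, tol: float = 1e-12, max_outer: int | None = None) -> np.ndarray:
    """Return ``Z >= 0`` minimizing ``||A Z - B||_F`` column-wise.

    Parameters
    ----------
    A : (p, q) array
    B : (p, k) array
    tol : float
        Feasibility tolerance on primal/dual violations, scaled by the
        magnitude of the normal-equation data.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    p, q = A.shape
    k = B.shape[1]
    AtA = A.T @ A
    AtB = A.T @ B
    scale = max(np.abs(AtA).max(), np.abs(AtB).max() if AtB.size else 0.0, 1.0)
    eps = tol * scale

    Z = np.zeros((q, k))
    Y = -AtB.copy()          # dual Y = AtA Z - AtB at Z = 0
    F = np.zeros((q, k), dtype=bool)
    alpha = np.full(k, 3)
    beta = np.full(k, q + 1)

    if max_outer is None:
        max_outer = 10 * q + 100

    for _ in range(max_outer):
        infeas = (F & (Z < -eps)) | (~F & (Y < -eps))
        bad_cols = np.flatnonzero(infeas.any(axis=0))
        if bad_cols.size == 0:
            Z[Z < 0] = 0.0
            return Z
        for j in bad_cols:
            v = infeas[:, j]
            nv = int(v.sum())
            if nv < beta[j]:
                beta[j] = nv
                alpha[j] = 3
                F[v, j] ^= True
            elif alpha[j] >= 1:
                alpha[j] -= 1
                F[v, j] ^= True
            else:
                # backup rule: flip only the largest infeasible index
                i = int(np.flatnonzero(v)[-1])
                F[i, j] ^= True
        _solve_passive(AtA, AtB, F, Z)
        Y = AtA @ Z - AtB
        Y[F] = 0.0
        Z[~F] = 0.0

    # columns still infeasible: hand them to the reference dense solver
    infeas = (F & (Z < -eps)) | (~F & (Y < -eps))
    for j in np.flatnonzero(infeas.any(axis=0)):
        try:
            Z[:, j] = scipy.optimize.nnls(A, B[:, j])[0]
        except Exception as exc:  # pragma: no cover - scipy failure is exotic
            raise NNLSError(int(j), str(exc)) from exc
    Z[Z < 0] = 0.0
    return Z
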