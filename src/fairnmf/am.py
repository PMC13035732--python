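"""Fairer-NMF by alternating minimization.

The objective is the min-max relative loss

    f(W, H) = max_l (‖X_l − W_l H‖ − E_l) / ‖X_l‖ .

With W fixed, minimizing f over H ≥ 0 is a second-order cone program in
epigraph form:

    min t   s.t.  ‖X_l − W_l H‖ ≤ t ‖X_l‖ + E_l   for every group l,  H ≥ 0.

With H fixed, W is under-determined by f alone (only the worst group pins its
block down), so W is chosen as the full NNLS minimizer of ‖X − W H‖², which
solves min_{W_l} ‖X_l − W_l H‖ for every group independently.  Both steps can
only decrease f — the H-step by construction, the W-step because it shrinks
every group's error — so the f-trace is non-increasing.

Each cone is compressed through a thin QR of the group's W block:
‖X_l − W_l H‖² = ‖Q_lᵀX_l − R_l H‖² + d_l², shrinking the cone dimension
from m_l·n+1 to r·n+2 independently of the group size.

The primary conic solver is ECOS; on any non-optimal status the step is
retried with a scipy SLSQP epigraph solve (warm-started at the incumbent H,
which also guarantees the step never worsens f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .data import Factorization, GroupedMatrix, objective_f
from .nmf import FitConfig, FitResult, _finalize, _relative_group_errors, init_factors, nnls_w, stopping_met

try:  # hard dependency in practice; guarded so the fallback path still works
    import ecos

    _HAVE_ECOS = True
except ImportError:  # pragma: no cover
    _HAVE_ECOS = False

__all__ = ["ConicSolveReport", "solve_h_minmax", "solve_w_step", "fit_fairer_am"]


class ConicSolverError(RuntimeError):
    """Both the primary and fallback H-step solvers failed."""


@dataclass(frozen=True)
class ConicSolveReport:
    """Outcome of one H-step: which solver ran, its status, the epigraph
    value t (the achieved min-max loss), and its iteration count."""

    solver: str
    status: str
    t: float
    iterations: int


def _group_qr(G: GroupedMatrix, W: np.ndarray):
    """Per-group compressed residual data (R_l, B_l = Q_lᵀ X_l, offset d_l)."""
    out = []
    for idx in G.group_indices:
        Wl = W[idx]
        Xl = G.X[idx]
        Q, R = np.linalg.qr(Wl)
        B = Q.T @ Xl
        d2 = max(np.linalg.norm(Xl) ** 2 - np.linalg.norm(B) ** 2, 0.0)
        out.append((R, B, float(np.sqrt(d2))))
    return out


def _solve_ecos(qr_data, norms, E, r, n):
    nh = r * n
    nvar = nh + 1
    c = np.zeros(nvar)
    c[-1] = 1.0

    blocks_G = [sp.hstack([-sp.eye(nh), sp.csc_matrix((nh, 1))])]
    blocks_h = [np.zeros(nh)]
    q_dims = []
    for (R, B, d), norm_l, E_l in zip(qr_data, norms, E):
        k = R.shape[0]
        # s0 = E_l + norm_l * t
        row_t = sp.csc_matrix(
            (np.array([-norm_l]), (np.array([0]), np.array([nvar - 1]))),
            shape=(1, nvar),
        )
        # s_mid = vec_F(B) − (I_n ⊗ R) h   (column-major vectorization)
        K = sp.kron(sp.eye(n), sp.csc_matrix(R))
        mid = sp.hstack([K, sp.csc_matrix((k * n, 1))])
        # s_last = d (constant)
        last = sp.csc_matrix((1, nvar))
        blocks_G.extend([row_t, mid, last])
        blocks_h.extend([np.array([E_l]), B.flatten(order="F"), np.array([d])])
        q_dims.append(1 + k * n + 1)

    Gmat = sp.vstack(blocks_G).tocsc()
    hvec = np.concatenate(blocks_h)
    dims = {"l": nh, "q": q_dims}
    sol = ecos.solve(c, Gmat, hvec, dims, verbose=False)
    flag = sol["info"]["exitFlag"]
    status = {0: "optimal", 10: "inaccurate"}.get(flag, f"failed({flag})")
    H = np.maximum(sol["x"][:nh].reshape(r, n, order="F"), 0.0)
    t = float(sol["x"][-1])
    iters = int(sol["info"].get("iter", -1))
    return H, t, status, iters


def _solve_slsqp(qr_data, norms, E, r, n, H0, t0):
    nh = r * n

    def split(z):
        return z[:nh].reshape(r, n), z[nh]

    def cons_f(z, R, B, d, norm_l, E_l):
        Hm, t = split(z)
        s = np.sqrt(np.linalg.norm(B - R @ Hm) ** 2 + d * d)
        return E_l + norm_l * t - s

    def cons_jac(z, R, B, d, norm_l, E_l):
        Hm, _ = split(z)
        res = B - R @ Hm
        s = np.sqrt(np.linalg.norm(res) ** 2 + d * d)
        g = np.zeros(nh + 1)
        if s > 0:
            g[:nh] = (R.T @ res).ravel() / s
        g[nh] = norm_l
        return g

    constraints = [
        {
            "type": "ineq",
            "fun": cons_f,
            "jac": cons_jac,
            "args": (R, B, d, float(nl), float(El)),
        }
        for (R, B, d), nl, El in zip(qr_data, norms, E)
    ]
    z0 = np.concatenate([H0.ravel(), [t0 + 1e-8]])
    bounds = [(0.0, None)] * nh + [(None, None)]
    obj_grad = np.zeros(nh + 1)
    obj_grad[-1] = 1.0
    res = scipy.optimize.minimize(
        lambda z: z[-1],
        z0,
        jac=lambda z: obj_grad,
        bounds=bounds,
        constraints=constraints,
        method="SLSQP",
        options={"maxiter": 300, "ftol": 1e-10},
    )
    Hm, t = split(res.x)
    H = np.maximum(Hm, 0.0)
    status = "optimal" if res.success else f"failed({res.status})"
    return H, float(t), status, int(res.nit)


def solve_h_minmax(G: GroupedMatrix, W: np.ndarray, E, H_init: np.ndarray | None = None):
    """Minimize the max relative loss over H ≥ 0 with W fixed.

    Returns ``(H, ConicSolveReport)``.  The reported ``t`` is the achieved
    objective recomputed from the returned (clipped) H, so it is consistent
    with :func:`fairnmf.data.objective_f` by construction.  If the primary
    conic solver does not return an optimal status the fallback epigraph
    solve runs; if both fail a :class:`ConicSolverError` is raised.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (G.L,):
        raise ValueError(f"E has shape {E.shape}, expected ({G.L},)")
    W = np.asarray(W, dtype=float)
    r, n = W.shape[1], G.n
    norms = G.group_norms
    qr_data = _group_qr(G, W)

    H = t = None
    solver = status = None
    iters = -1
    if _HAVE_ECOS:
        try:
            H, t, status, iters = _solve_ecos(qr_data, norms, E, r, n)
            solver = "ecos"
        except Exception:
            status = "failed(exception)"
    if H is None or status != "optimal":
        H0 = H_init if H_init is not None else (H if H is not None else np.zeros((r, n)))
        t0 = _achieved(G, W, H0, E) if H0 is not None else 0.0
        H_fb, t_fb, status_fb, iters_fb = _solve_slsqp(qr_data, norms, E, r, n, H0, t0)
        if status_fb == "optimal" or H is None:
            H, t, status, iters = H_fb, t_fb, status_fb, iters_fb
            solver = "fallback-slsqp"
        if "failed" in status:
            raise ConicSolverError(
                f"H-step failed on both solvers (last status: {status})"
            )
    t_achieved = _achieved(G, W, H, E)
    return H, ConicSolveReport(solver=solver, status=status, t=t_achieved, iterations=iters)


def _achieved(G: GroupedMatrix, W: np.ndarray, H: np.ndarray, E: np.ndarray) -> float:
    R = G.X - W @ H
    losses = [
        (np.linalg.norm(R[idx]) - El) / nl
        for idx, El, nl in zip(G.group_indices, E, G.group_norms)
    ]
    return float(max(losses))


def solve_w_step(G: GroupedMatrix, H: np.ndarray) -> np.ndarray:
    """W-step: full NNLS of X against H.

    Row-separability makes this identical to solving each group block — and
    indeed each sample — independently, which is exactly the W-selection rule
    that resolves the under-determination of W in the min-max objective.
    """
    return nnls_w(G.X, H)


def fit_fairer_am(G: GroupedMatrix, E, config: FitConfig) -> FitResult:
    """Alternating minimization for Fairer-NMF.

    Starts from a random H (uniform(0,1) entries) with W immediately set by
    the NNLS W-step, then alternates the SOCP H-step and the NNLS W-step
    until the per-group stopping rule fires or ``max_iter`` is reached.
    The recorded f-trace is non-increasing up to solver tolerance.
    """
    E = np.asarray(getattr(E, "E", E), dtype=float)
    H = init_factors(G.m, G.n, config.rank, config.seed).H
    W = solve_w_step(G, H)
    trace = [_relative_group_errors(G, W, H)]
    reports = []
    converged = False
    for _ in range(config.max_iter):
        f_before = _achieved(G, W, H, E)
        H_new, report = solve_h_minmax(G, W, E, H_init=H)
        # solvers are approximate: never accept a step that worsens f
        if report.t <= f_before + 1e-12:
            H = H_new
        reports.append(report)
        W = solve_w_step(G, H)
        trace.append(_relative_group_errors(G, W, H))
        if stopping_met(trace[-2], trace[-1], config):
            converged = True
            break
    return _finalize(
        G, W, H, trace, converged, "fairer-am", E, extras={"solver_reports": reports}
    )
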