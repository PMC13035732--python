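"""Standard rank-r NMF: argmin_{W,H >= 0} ||X - W H||².

Two solvers are provided, both tracking per-group reconstruction errors:

* ``mu`` — Lee–Seung multiplicative updates, one W sweep then one H sweep
  per iteration; cheap, non-negativity is preserved by construction and the
  squared Frobenius objective is non-increasing.
* ``am`` — alternating minimization by exact non-negative least squares,
  W-step then H-step; each step is a convex solve so the objective is
  non-increasing up to solver tolerance.

The stopping rule is per-group: iterate until, for every group, the change
of its reconstruction error within one iteration is at most ``rel_change_tol``
times the current error, or (when the error floor is enabled) the group's
relative error has dropped below the floor.  Exactly reconstructible data —
e.g. the synthetic benchmarks at high enough rank — is the case the floor
exists for, since the relative-change ratio never settles at error ≈ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._nnls import nnls_multi
from .data import Factorization, GroupedMatrix, MetricTable, compute_metrics

__all__ = [
    "FitConfig",
    "FitResult",
    "init_factors",
    "mu_update_w",
    "mu_update_h",
    "nnls_w",
    "nnls_h",
    "stopping_met",
    "fit_standard",
]


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration shared by standard and fairer fits.

    Parameters
    ----------
    rank : int
        Target rank r of the factorization.
    method : str
        ``"mu"`` or ``"am"`` (for the standard solver).
    max_iter : int
        Iteration cap; hitting it sets ``converged=False`` on the result.
    rel_change_tol : float
        Per-group relative-change stopping threshold (default 1e-4).
    error_floor_pct : float or None
        When set (in percent, e.g. 0.1), a group whose relative error falls
        below the floor counts as converged regardless of its change.  Off
        by default; meant for exactly factorable (synthetic) data.
    seed : int or numpy SeedSequence
        Seed for the uniform(0,1) factor initialization.
    eps : float
        Relative guard added to MU denominators (scaled by the denominator's
        largest entry, so updates are invariant to a global rescaling).
    c_rule : str
        ``"decreasing"`` or ``"exact"`` — group-weight schedule used only by
        the fairer multiplicative-updates solver.
    """

    rank: int
    method: str = "mu"
    max_iter: int = 500
    rel_change_tol: float = 1e-4
    error_floor_pct: float | None = None
    seed: int | np.random.SeedSequence = 0
    eps: float = 1e-10
    c_rule: str = "decreasing"

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.method not in {"mu", "am"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.rel_change_tol <= 0:
            raise ValueError("rel_change_tol must be positive")
        if self.error_floor_pct is not None and self.error_floor_pct <= 0:
            raise ValueError("error_floor_pct must be positive when set")
        if self.c_rule not in {"decreasing", "exact"}:
            raise ValueError(f"unknown c_rule {self.c_rule!r}")

    def with_seed(self, seed) -> "FitConfig":
        return replace(self, seed=seed)


@dataclass
class FitResult:
    """Fitted factors plus per-iteration diagnostics.

    ``error_trace[k, l]`` is group l's relative reconstruction error after
    iteration k (row 0 is the random initialization).  ``loss_trace`` and
    ``f_trace`` are present whenever baseline errors were supplied.
    """

    factorization: Factorization
    error_trace: np.ndarray
    converged: bool
    n_iter: int
    method: str
    loss_trace: np.ndarray | None = None
    f_trace: np.ndarray | None = None
    metrics: MetricTable | None = None
    extras: dict = field(default_factory=dict)

    @property
    def W(self) -> np.ndarray:
        return self.factorization.W

    @property
    def H(self) -> np.ndarray:
        return self.factorization.H

    def export(self, out_prefix, seed=None) -> list:
        """Write factors as CSV (W and H separately) plus a JSON sidecar with
        the method, rank, seed, convergence flag and all per-iteration traces
        (per-group errors/losses, f, weight trajectory, solver statuses)."""
        import dataclasses as _dc
        import json
        from pathlib import Path

        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        w_path = out_prefix.with_name(out_prefix.name + "_W.csv")
        h_path = out_prefix.with_name(out_prefix.name + "_H.csv")
        np.savetxt(w_path, self.W, delimiter=",")
        np.savetxt(h_path, self.H, delimiter=",")

        def _ser(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if _dc.is_dataclass(v):
                return _dc.asdict(v)
            if isinstance(v, (list, tuple)):
                return [_ser(x) for x in v]
            return v

        meta = {
            "method": self.method,
            "rank": int(self.factorization.rank),
            "seed": _ser(seed),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "error_trace": self.error_trace.tolist(),
            "loss_trace": _ser(self.loss_trace),
            "f_trace": _ser(self.f_trace),
            "extras": {k: _ser(v) for k, v in self.extras.items()},
        }
        j_path = out_prefix.with_suffix(".json")
        j_path.write_text(json.dumps(meta, indent=2))
        return [w_path, h_path, j_path]


def init_factors(m: int, n: int, r: int, seed) -> Factorization:
    """Random factors with i.i.d. uniform(0,1) entries; strictly positive so
    multiplicative updates never start pinned at a zero."""
    if min(m, n, r) < 1:
        raise ValueError("m, n, r must all be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(m, r))
    H = rng.uniform(size=(r, n))
    return Factorization(W, H)


def _guarded(den: np.ndarray, eps: float) -> np.ndarray:
    scale = den.max()
    return den + eps * (scale if scale > 0 else 1.0)


def mu_update_w(X, W, H, eps: float = 1e-10) -> np.ndarray:
    """One multiplicative W sweep: W ⊙ (X Hᵀ) / (W H Hᵀ)."""
    num = X @ H.T
    den = W @ (H @ H.T)
    return W * num / _guarded(den, eps)


def mu_update_h(X, W, H, eps: float = 1e-10) -> np.ndarray:
    """One multiplicative H sweep: H ⊙ (Wᵀ X) / (Wᵀ W H)."""
    num = W.T @ X
    den = (W.T @ W) @ H
    return H * num / _guarded(den, eps)


def nnls_w(X, H) -> np.ndarray:
    """Exact W-step: per-row NNLS of X against Hᵀ (row-separable)."""
    return nnls_multi(np.asarray(H, dtype=float).T, np.asarray(X, dtype=float).T).T


def nnls_h(X, W) -> np.ndarray:
    """Exact H-step: per-column NNLS of X against W (column-separable)."""
    return nnls_multi(np.asarray(W, dtype=float), np.asarray(X, dtype=float))


def stopping_met(
    prev_errors: Sequence[float], curr_errors: Sequence[float], config: FitConfig
) -> bool:
    """Per-group convergence test.

    True iff every group satisfies |e_k − e_{k−1}| / e_k < rel_change_tol,
    or (floor enabled) its relative error is below the floor.  The ratio is
    scale-free, so relative and unnormalized errors are interchangeable here
    as long as both vectors use the same scale.  A group whose current error
    is exactly zero counts as converged (the ratio is undefined at 0 and the
    reconstruction cannot improve).
    """
    prev = np.asarray(prev_errors, dtype=float)
    curr = np.asarray(curr_errors, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError("error vectors must have matching length")
    for e_prev, e_curr in zip(prev, curr):
        if e_curr == 0:
            continue
        if (
            config.error_floor_pct is not None
            and e_curr * 100.0 < config.error_floor_pct
        ):
            continue
        if abs(e_curr - e_prev) / e_curr < config.rel_change_tol:
            continue
        return False
    return True


def _relative_group_errors(G: GroupedMatrix, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    R = G.X - W @ H
    return np.array(
        [np.linalg.norm(R[idx]) for idx in G.group_indices]
    ) / G.group_norms


def _finalize(
    G: GroupedMatrix,
    W: np.ndarray,
    H: np.ndarray,
    trace: list[np.ndarray],
    converged: bool,
    method: str,
    E,
    extras: dict | None = None,
) -> FitResult:
    fact = Factorization(W, H)
    err = np.vstack(trace)
    res = FitResult(
        factorization=fact,
        error_trace=err,
        converged=converged,
        n_iter=err.shape[0] - 1,
        method=method,
        extras=extras or {},
    )
    if E is not None:
        E = np.asarray(E, dtype=float)
        norms = G.group_norms
        res.loss_trace = (err * norms - E) / norms
        res.f_trace = res.loss_trace.max(axis=1)
        res.metrics = compute_metrics(G, fact, E)
    return res


def fit_standard(G: GroupedMatrix, config: FitConfig, E=None) -> FitResult:
    """Standard NMF of the full matrix, tracking per-group errors.

    The objective is the global squared error (which equals the sum of the
    per-group squared errors, the blocks being a row partition); stopping is
    per-group so standard and fairer fits share one convergence rule.  When
    ``E`` (per-group baseline errors) is given, loss and f traces and a final
    metric table are attached.
    """
    X = G.X
    fact = init_factors(G.m, G.n, config.rank, config.seed)
    W, H = fact.W, fact.H
    trace = [_relative_group_errors(G, W, H)]
    converged = False
    for _ in range(config.max_iter):
        if config.method == "mu":
            W = mu_update_w(X, W, H, config.eps)
            H = mu_update_h(X, W, H, config.eps)
        else:
            W = nnls_w(X, H)
            H = nnls_h(X, W)
        trace.append(_relative_group_errors(G, W, H))
        if stopping_met(trace[-2], trace[-1], config):
            converged = True
            break
    return _finalize(G, W, H, trace, converged, f"standard-{config.method}", E)
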