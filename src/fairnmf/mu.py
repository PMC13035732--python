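"""Fairer-NMF by weighted multiplicative updates.

The min-max loss can be written as a maximum over simplex weights c of the
weighted sum  Σ_l c_l (‖X_l − W_l H‖ − E_l)/‖X_l‖.  The scheme alternates:

1. pick the worst-off group  l* = argmax_l loss_l  (the exact maximizer of
   the weighted form is the vertex e_{l*});
2. move the weight vector toward that vertex with a decreasing step size —
   implemented in the equivalent unnormalized form  c ← c + e_{l*}  (the
   H update below is invariant to positive rescaling of c, so keeping
   ‖c‖₁ = 1 is unnecessary);
3. update H by one standard multiplicative sweep on the stacked surrogate
   ‖X̃ − W̃H‖², where X̃ and W̃ stack the group blocks scaled by c_l/‖X_l‖ —
   a tractable proxy for the weighted sum of unsquared norms;
4. update each W_l by one multiplicative sweep on its own unscaled block
   X_l ≈ W_l H.

Jumping all the way to the vertex each iteration ("exact-c" mode, available
behind ``FitConfig.c_rule = "exact"``) makes the worst group oscillate and
convergence erratic; it is included only for comparison.  Unlike the
alternating-minimization scheme, no monotone decrease of f is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Factorization, GroupedMatrix, compute_metrics
from .nmf import (
    FitConfig,
    FitResult,
    _finalize,
    _relative_group_errors,
    init_factors,
    mu_update_h,
    mu_update_w,
    stopping_met,
)

__all__ = [
    "FairerMUState",
    "StackedPair",
    "select_worst_group",
    "update_c",
    "build_stacked",
    "mu_step",
    "fit_fairer_mu",
]


@dataclass(frozen=True)
class FairerMUState:
    """Unnormalized group weights plus iteration bookkeeping.

    ``c`` starts at zero and gains one unit per iteration on the worst-off
    group, so after k iterations its entries sum to k; dividing by k
    recovers the normalized decreasing-step-size rule exactly.
    """

    c: np.ndarray
    k: int = 0
    worst_history: tuple = ()

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if np.any(c < 0):
            raise ValueError("group weights must be non-negative")
        if self.k > 0 and c.sum() == 0:
            raise ValueError("c can only be all-zero at k = 0")
        object.__setattr__(self, "c", c)

    @classmethod
    def initial(cls, L: int) -> "FairerMUState":
        return cls(c=np.zeros(L), k=0, worst_history=())


@dataclass(frozen=True)
class StackedPair:
    """The c-weighted stacked matrices X̃ = [c_l X_l/‖X_l‖] and
    W̃ = [c_l W_l/‖X_l‖], blocks in group order."""

    X_tilde: np.ndarray
    W_tilde: np.ndarray


#: Fraction of the total weight mass spread uniformly over all groups when
#: building the stacked surrogate.  Multiplicative updates make exact zeros
#: absorbing: with single-vertex weights (the first iterations, or the whole
#: run in exact-c mode) and groups on orthogonal feature supports, one
#: stacked H sweep would zero the unweighted groups' dictionary columns
#: *exactly*, and weight assigned to them later could never resurrect those
#: columns — the fit would deadlock at loss ≈ 1.  Mixing a small uniform
#: component into c keeps every group's numerator positive, bounding the
#: per-sweep shrinkage of an unweighted group's columns so they remain
#: recoverable, at the price of a ≤ (mix/L)² relative bias in the surrogate
#: weights at convergence.
WEIGHT_MIXING = 0.05


def _mixed_weights(c: np.ndarray, mixing: float) -> np.ndarray:
    """c plus a uniform share of its own mass (linear in c, so the H update
    stays invariant under positive rescaling)."""
    if mixing <= 0:
        return c
    return c + (mixing / c.shape[0]) * c.sum()


def select_worst_group(G: GroupedMatrix, F: Factorization, E) -> int:
    """Index of the group with the largest relative loss (lowest index wins ties)."""
    E = np.asarray(getattr(E, "E", E), dtype=float)
    return compute_metrics(G, F, E).worst_group


def update_c(state: FairerMUState, worst: int) -> FairerMUState:
    """Accumulate one unit of weight on the worst group: c ← c + e_{l*}."""
    if not 0 <= worst < state.c.shape[0]:
        raise IndexError(f"group index {worst} out of range for L={state.c.shape[0]}")
    c = state.c.copy()
    c[worst] += 1.0
    return FairerMUState(c=c, k=state.k + 1, worst_history=state.worst_history + (worst,))


def build_stacked(G: GroupedMatrix, F: Factorization, c) -> StackedPair:
    """Assemble the stacked surrogate matrices for weight vector c.

    Groups with c_l = 0 contribute zero blocks; an all-zero c leaves no
    surrogate to minimize and is rejected.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (G.L,):
        raise ValueError(f"c has shape {c.shape}, expected ({G.L},)")
    if np.any(c < 0):
        raise ValueError("c must be non-negative")
    if c.sum() == 0:
        raise ValueError("c must not be all zero")
    norms = G.group_norms
    scale_rows = np.empty(G.m)
    for l, idx in enumerate(G.group_indices):
        scale_rows[idx] = c[l] / norms[l]
    return StackedPair(
        X_tilde=G.X * scale_rows[:, None], W_tilde=F.W * scale_rows[:, None]
    )


def mu_step(
    G: GroupedMatrix,
    F: Factorization,
    state: FairerMUState,
    E,
    eps: float = 1e-10,
    c_rule: str = "decreasing",
    mixing: float = WEIGHT_MIXING,
):
    """One full fairer-MU iteration.

    Selects the worst group, updates the weights, performs one H sweep on
    the stacked surrogate (with a small uniform component mixed into the
    weights, see :data:`WEIGHT_MIXING`) and one W sweep per group on the
    unscaled blocks.  The unnormalized weights are used as-is: the H update
    is invariant to a positive rescaling of c (the denominator guard scales
    with the denominator), so accumulation and the normalized
    decreasing-step rule produce the same iterates.
    """
    E = np.asarray(getattr(E, "E", E), dtype=float)
    worst = select_worst_group(G, F, E)
    if c_rule == "exact":
        c_next = np.zeros(G.L)
        c_next[worst] = 1.0
        state = FairerMUState(
            c=c_next, k=state.k + 1, worst_history=state.worst_history + (worst,)
        )
    else:
        state = update_c(state, worst)
    # exact-c mode demonstrates the failure of pure vertex weights, so the
    # mixing safeguard is deliberately not applied there
    use_mixing = 0.0 if c_rule == "exact" else mixing
    stacked = build_stacked(G, F, _mixed_weights(state.c, use_mixing))
    H_new = mu_update_h(stacked.X_tilde, stacked.W_tilde, F.H, eps)
    W_new = np.empty_like(F.W)
    for idx in G.group_indices:
        W_new[idx] = mu_update_w(G.X[idx], F.W[idx], H_new, eps)
    return Factorization(W_new, H_new), state


def fit_fairer_mu(G: GroupedMatrix, E, config: FitConfig) -> FitResult:
    """Weighted multiplicative updates for Fairer-NMF.

    Iterates :func:`mu_step` from a random uniform(0,1) initialization until
    the per-group stopping rule fires or ``max_iter`` is reached.  The
    f-trace is recorded but not guaranteed monotone.  The c trajectory and
    the worst-group history are stored in ``extras``.
    """
    E_arr = np.asarray(getattr(E, "E", E), dtype=float)
    F = init_factors(G.m, G.n, config.rank, config.seed)
    state = FairerMUState.initial(G.L)
    trace = [_relative_group_errors(G, F.W, F.H)]
    c_trace = [state.c.copy()]
    converged = False
    for _ in range(config.max_iter):
        F, state = mu_step(G, F, state, E_arr, eps=config.eps, c_rule=config.c_rule)
        trace.append(_relative_group_errors(G, F.W, F.H))
        c_trace.append(state.c.copy())
        if stopping_met(trace[-2], trace[-1], config):
            converged = True
            break
    return _finalize(
        G,
        F.W,
        F.H,
        trace,
        converged,
        "fairer-mu",
        E_arr,
        extras={
            "c_trace": np.vstack(c_trace),
            "worst_history": state.worst_history,
        },
    )
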