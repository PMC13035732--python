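"""Per-group baseline errors E_l.

The fairness loss compares a group's error inside the shared factorization
with E_l, the error the group would expect from a rank-r NMF trained on its
own block alone.  Finding the optimal standalone error is NP-hard, so E_l is
defined as the expectation of the achieved error of a *randomized* standalone
NMF — estimated here by averaging T independent runs (random uniform
initialization, fresh seed per run).

Because E_l is an average over a particular randomized solver, it is an
upper-bound-style reference, not a lower bound: a shared model found by a
different method can beat it, making that group's loss negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data import GroupedMatrix
from .nmf import FitConfig, fit_standard

__all__ = ["BaselineErrors", "estimate_group_baseline", "estimate_all_baselines"]


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from a tuple of ints/strings."""
    import zlib

    entropy = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            entropy.append(int(p) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(p).encode()))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class BaselineErrors:
    """The vector (E_1, ..., E_L) of per-group standalone NMF errors.

    ``E`` is on the unsquared Frobenius scale, matching the loss numerator.
    ``seeds[l]`` records the T per-run seeds used for group l, so any entry
    is reproducible bit-for-bit.
    """

    E: np.ndarray
    T: int
    rank: int
    seeds: tuple
    all_converged: bool = True

    def __post_init__(self):
        E = np.asarray(self.E, dtype=float)
        if np.any(E < 0):
            raise ValueError("baseline errors must be non-negative")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        object.__setattr__(self, "E", E)

    @property
    def L(self) -> int:
        return self.E.shape[0]

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "E": self.E.tolist(),
                    "T": self.T,
                    "rank": self.rank,
                    "seeds": [list(s) for s in self.seeds],
                    "all_converged": self.all_converged,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path) -> "BaselineErrors":
        d = json.loads(Path(path).read_text())
        return cls(
            E=np.asarray(d["E"], dtype=float),
            T=int(d["T"]),
            rank=int(d["rank"]),
            seeds=tuple(tuple(s) for s in d["seeds"]),
            all_converged=bool(d.get("all_converged", True)),
        )


def estimate_group_baseline(
    X_sub: np.ndarray, config: FitConfig, T: int = 5, seed: int = 0
):
    """Mean achieved error of T standalone NMF runs on one group block.

    Each run fits rank-r NMF on ``X_sub`` alone (multiplicative updates by
    default — the low-cost solver — with the same stopping configuration as
    the main fits) from an independent derived seed, and contributes its
    unsquared final error ``‖X_sub − W*H*‖``.  Non-converged runs are still
    averaged; their presence is reported in the returned flag.

    Returns
    -------
    (E, run_seeds, all_converged)
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X_sub = np.asarray(X_sub, dtype=float)
    norm = np.linalg.norm(X_sub)
    if norm == 0:
        raise ZeroDivisionError("baseline undefined for an all-zero group block")
    G1 = GroupedMatrix(X_sub, np.zeros(X_sub.shape[0], dtype=int))
    errors = []
    run_seeds = []
    all_converged = True
    for t in range(T):
        s = derive_seed(seed, t)
        run_seeds.append(s)
        res = fit_standard(G1, config.with_seed(s))
        errors.append(res.error_trace[-1, 0] * norm)
        all_converged = all_converged and res.converged
    return float(np.mean(errors)), tuple(run_seeds), all_converged


def estimate_all_baselines(
    G: GroupedMatrix, config: FitConfig, T: int = 5, seed: int = 0
) -> BaselineErrors:
    """Estimate E_l for every group of ``G`` with independent derived seeds."""
    E = np.empty(G.L)
    seeds = []
    all_conv = True
    for l in range(G.L):
        E[l], s, conv = estimate_group_baseline(
            G.block(l), config, T=T, seed=derive_seed(seed, l)
        )
        seeds.append(s)
        all_conv = all_conv and conv
    return BaselineErrors(
        E=E, T=T, rank=config.rank, seeds=tuple(seeds), all_converged=all_conv
    )
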