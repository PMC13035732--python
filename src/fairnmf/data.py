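"""Core containers and metrics for grouped non-negative data.

A dataset is a non-negative matrix ``X`` (rows = samples, columns = features)
together with an exhaustive, mutually exclusive partition of the rows into
``L`` groups.  Two metrics drive everything else:

* the *relative reconstruction error* of a block, ``‖X_l − W_l H‖ / ‖X_l‖``
  (Frobenius norms, unsquared), and
* the *relative reconstruction loss*, ``(‖X_l − W_l H‖ − E_l) / ‖X_l‖``,
  which measures the excess of a group's error in the shared factorization
  over ``E_l``, the error the group would expect from a standalone rank-r
  NMF of its own block.  The loss can be negative: sharing a model with
  other groups sometimes *helps*.

The min-max fairness objective is ``f = max_l loss_l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupedMatrix",
    "Factorization",
    "MetricTable",
    "normalize_features",
    "relative_error",
    "relative_loss",
    "objective_f",
    "compute_metrics",
    "read_grouped_csv",
    "write_metric_table",
]


def _as_nonnegative_array(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {X.shape}")
    if np.any(X < 0):
        raise ValueError(f"{name} must be entrywise non-negative")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


@dataclass(frozen=True)
class GroupedMatrix:
    """A non-negative data matrix with a row partition into groups.

    Parameters
    ----------
    X : (m, n) array
        Non-negative data, rows are samples.
    group_labels : sequence of length m
        One categorical label per row.  Group order is the order of first
        appearance of each label, and is preserved in every per-group output.
    """

    X: np.ndarray
    group_labels: np.ndarray
    groups: tuple = field(init=False)
    group_indices: tuple = field(init=False)

    def __post_init__(self):
        X = _as_nonnegative_array(self.X)
        labels = np.asarray(self.group_labels)
        if labels.shape != (X.shape[0],):
            raise ValueError(
                f"group_labels has shape {labels.shape}, expected ({X.shape[0]},)"
            )
        # order of first appearance, not lexicographic
        _, first = np.unique(labels, return_index=True)
        groups = tuple(labels[i] for i in np.sort(first))
        indices = tuple(np.flatnonzero(labels == g) for g in groups)
        for g, idx in zip(groups, indices):
            if np.linalg.norm(X[idx]) == 0:
                raise ValueError(
                    f"group {g!r} has zero Frobenius norm; metrics are undefined"
                )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "group_labels", labels)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "group_indices", indices)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([len(idx) for idx in self.group_indices])

    @property
    def group_norms(self) -> np.ndarray:
        """Frobenius norm ‖X_l‖ of each group block."""
        return np.array([np.linalg.norm(self.X[idx]) for idx in self.group_indices])

    def block(self, l: int) -> np.ndarray:
        """The group-l submatrix X_l (rows in original order)."""
        return self.X[self.group_indices[l]]

    def blocks(self) -> list[np.ndarray]:
        return [self.X[idx] for idx in self.group_indices]

    def normalized(self) -> "GroupedMatrix":
        """Feature-normalized copy (unit ℓ2 columns, computed on the full X)."""
        return GroupedMatrix(normalize_features(self.X), self.group_labels)

    def single_group(self, l: int) -> "GroupedMatrix":
        """Group l as a standalone one-group dataset."""
        idx = self.group_indices[l]
        return GroupedMatrix(self.X[idx], self.group_labels[idx])


@dataclass(frozen=True)
class Factorization:
    """A rank-r NMF pair: X ≈ W H with W (m×r) the representation matrix
    and H (r×n) the dictionary matrix, both entrywise non-negative."""

    W: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        W = _as_nonnegative_array(self.W, "W")
        H = _as_nonnegative_array(self.H, "H")
        if W.shape[1] != H.shape[0]:
            raise ValueError(
                f"rank mismatch: W is {W.shape}, H is {H.shape}"
            )
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "H", H)

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass(frozen=True)
class MetricTable:
    """Per-group metrics of a factorization plus the min-max objective.

    ``f`` is the maximum relative loss over groups; ``worst_group`` is the
    index attaining it (ties broken toward the lowest group index).
    """

    groups: tuple
    relative_errors: np.ndarray
    relative_losses: np.ndarray
    f: float
    worst_group: int

    def to_frame(self, rank: int | None = None, trial: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": list(self.groups),
                "relative_error": self.relative_errors,
                "relative_loss": self.relative_losses,
                "f": self.f,
            }
        )
        if rank is not None:
            df.insert(1, "rank", rank)
        if trial is not None:
            df.insert(2 if rank is not None else 1, "trial", trial)
        return df


def normalize_features(X) -> np.ndarray:
    """Scale every column of ``X`` to unit Euclidean norm.

    All-zero columns are returned unchanged (there is nothing to scale and
    0/0 would otherwise poison the matrix).  Applied to the full matrix
    before any group split; column scaling commutes with row partitioning.
    """
    X = _as_nonnegative_array(X)
    norms = np.linalg.norm(X, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    return X / scale


def relative_error(X_sub, W_sub, H) -> float:
    """‖X_sub − W_sub H‖ / ‖X_sub‖ with Frobenius norms (unsquared)."""
    X_sub = np.asarray(X_sub, dtype=float)
    denom = np.linalg.norm(X_sub)
    if denom == 0:
        raise ZeroDivisionError(
            "relative_error undefined: ‖X_sub‖ = 0 (empty or all-zero block)"
        )
    return float(np.linalg.norm(X_sub - np.asarray(W_sub) @ np.asarray(H)) / denom)


def relative_loss(X_sub, W_sub, H, E_sub: float) -> float:
    """(‖X_sub − W_sub H‖ − E_sub) / ‖X_sub‖; may be negative.

    ``E_sub`` is the group's standalone baseline error (unsquared Frobenius
    scale, same units as the numerator's norm).
    """
    if E_sub < 0:
        raise ValueError("baseline error E_sub must be non-negative")
    X_sub = np.asarray(X_sub, dtype=float)
    denom = np.linalg.norm(X_sub)
    if denom == 0:
        raise ZeroDivisionError(
            "relative_loss undefined: ‖X_sub‖ = 0 (empty or all-zero block)"
        )
    err = np.linalg.norm(X_sub - np.asarray(W_sub) @ np.asarray(H))
    return float((err - E_sub) / denom)


def _per_group_errors(G: GroupedMatrix, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Unnormalized per-group errors ‖X_l − W_l H‖."""
    R = G.X - W @ H
    return np.array([np.linalg.norm(R[idx]) for idx in G.group_indices])


def compute_metrics(G: GroupedMatrix, F: Factorization, E: Sequence[float]) -> MetricTable:
    """Per-group relative errors and losses of ``F`` on ``G`` and f = max loss."""
    E = np.asarray(E, dtype=float)
    if E.shape != (G.L,):
        raise ValueError(f"E has shape {E.shape}, expected ({G.L},)")
    errs = _per_group_errors(G, F.W, F.H)
    norms = G.group_norms
    rel_err = errs / norms
    rel_loss = (errs - E) / norms
    worst = int(np.argmax(rel_loss))  # first max: lowest-index tie-break
    return MetricTable(
        groups=G.groups,
        relative_errors=rel_err,
        relative_losses=rel_loss,
        f=float(rel_loss[worst]),
        worst_group=worst,
    )


def objective_f(G: GroupedMatrix, F: Factorization, E: Sequence[float]) -> float:
    """The min-max objective f = max_l (‖X_l − W_l H‖ − E_l)/‖X_l‖."""
    return compute_metrics(G, F, E).f


def read_grouped_csv(
    path, group_col: str, sep: str | None = None
) -> GroupedMatrix:
    """Read a delimited table (header row required) into a :class:`GroupedMatrix`.

    ``group_col`` names the group-label column; every other column must parse
    as a non-negative real.  Row order defines sample indices.  ``sep=None``
    infers the delimiter from the file extension (TSV for .tsv, else CSV).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if group_col not in df.columns:
        raise ValueError(f"group column {group_col!r} not found in {path.name}")
    labels = df[group_col].to_numpy()
    feats = df.drop(columns=[group_col])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values in {path.name}: {exc}") from exc
    return GroupedMatrix(X, labels)


def write_metric_table(
    table: pd.DataFrame, out_prefix, formats: Sequence[str] = ("csv", "json")
) -> list[Path]:
    """Write a long-format metric table (group/rank/trial/relative_error/
    relative_loss/f columns) as CSV and/or JSON next to ``out_prefix``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = out_prefix.with_suffix(".csv")
        table.to_csv(p, index=False)
        written.append(p)
    if "json" in formats:
        p = out_prefix.with_suffix(".json")
        table.to_json(p, orient="records", indent=2)
        written.append(p)
    return written
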