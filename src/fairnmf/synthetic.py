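"""Synthetic grouped benchmark datasets.

Each group block is generated as X_l = W_l H_l where H_l is a fixed
non-negative dictionary (r_l × n) and each row of W_l is drawn independently
and uniformly from the standard basis vectors of ℝ^{r_l} — i.e. every sample
is a uniformly chosen row of H_l, optionally perturbed by additive Gaussian
noise truncated at zero.

Two ready-made datasets exercise the two failure modes of average-error NMF:

* :func:`gen_dataset1` — two orthogonal groups of 500 samples × 12 features
  that differ in complexity: a rank-6 group on features 1–6 and a rank-3
  group on features 7–12.  The combined matrix has non-negative rank 9, so
  an exact rank-9 factorization exists.
* :func:`gen_dataset2` — three groups of rank 3 each; groups 1 and 2 share
  one dictionary (group 2 gets Gaussian noise, sd 0.1, truncated at 0) and
  group 3 lives on orthogonal features, so two groups crowd one subspace.

Basis vectors are numbered 1-based in the documentation (e1…e12) and
0-based in the code; the conversion happens only in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GroupedMatrix

__all__ = [
    "GroupSpec",
    "gen_group",
    "make_grouped",
    "gen_dataset1",
    "gen_dataset2",
    "to_dataframe",
    "write_csv",
]

N_FEATURES = 12
GROUP_SIZE = 500


def _basis_rows(pairs, n: int = N_FEATURES) -> np.ndarray:
    """Dictionary rows as sums of 1-based basis vectors, e.g. [(7, 10), ...]."""
    H = np.zeros((len(pairs), n))
    for i, cols in enumerate(pairs):
        for c in cols:
            H[i, c - 1] = 1.0
    return H


@dataclass(frozen=True)
class GroupSpec:
    """One group of a synthetic dataset: its label, sample count, latent
    dictionary H_l and the standard deviation of the truncated Gaussian
    noise (0 = exact low-rank samples)."""

    label: str
    H: np.ndarray
    m: int = GROUP_SIZE
    noise_sd: float = 0.0

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if H.ndim != 2 or np.any(H < 0):
            raise ValueError("H must be a 2-D non-negative dictionary")
        if np.any(np.linalg.norm(H, axis=1) == 0):
            raise ValueError("dictionary rows must be non-zero")
        if self.m < H.shape[0]:
            raise ValueError("need at least one sample per latent topic")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "H", H)

    @property
    def latent_rank(self) -> int:
        return self.H.shape[0]


def gen_group(spec: GroupSpec, seed) -> np.ndarray:
    """Sample one group block: rows drawn uniformly from the rows of H_l,
    plus optional truncated Gaussian noise."""
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, spec.latent_rank, size=spec.m)
    X = spec.H[rows].copy()
    if spec.noise_sd > 0:
        X += rng.normal(0.0, spec.noise_sd, size=X.shape)
        np.maximum(X, 0.0, out=X)
    return X


def make_grouped(specs, seed) -> GroupedMatrix:
    """Stack independently generated group blocks into one GroupedMatrix."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    blocks, labels = [], []
    for spec, child in zip(specs, children):
        blocks.append(gen_group(spec, child))
        labels.extend([spec.label] * spec.m)
    return GroupedMatrix(np.vstack(blocks), np.array(labels))


def dataset1_specs() -> list[GroupSpec]:
    return [
        GroupSpec("group1", _basis_rows([(1,), (2,), (3,), (4,), (5,), (6,)])),
        GroupSpec("group2", _basis_rows([(7, 10), (8, 11), (9, 12)])),
    ]


def dataset2_specs() -> list[GroupSpec]:
    shared = _basis_rows([(1, 4), (2, 5), (3, 6)])
    return [
        GroupSpec("group1", shared),
        GroupSpec("group2", shared, noise_sd=0.1),
        GroupSpec("group3", _basis_rows([(7, 10), (8, 11), (9, 12)])),
    ]


def gen_dataset1(seed) -> GroupedMatrix:
    """Two orthogonal groups of different complexity (ranks 6 and 3)."""
    return make_grouped(dataset1_specs(), seed)


def gen_dataset2(seed) -> GroupedMatrix:
    """Three rank-3 groups; groups 1 and 2 share a subspace (group 2 noisy,
    Gaussian sd 0.1 truncated at 0), group 3 is orthogonal to both."""
    return make_grouped(dataset2_specs(), seed)


def to_dataframe(G: GroupedMatrix, group_col: str = "group") -> pd.DataFrame:
    """Long-format table with feature columns f1..fn plus the group column,
    matching the CSV dialect accepted by :func:`fairnmf.data.read_grouped_csv`."""
    df = pd.DataFrame(G.X, columns=[f"f{j + 1}" for j in range(G.n)])
    df[group_col] = G.group_labels
    return df


def write_csv(G: GroupedMatrix, path, group_col: str = "group") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    to_dataframe(G, group_col).to_csv(path, index=False)
    return path
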