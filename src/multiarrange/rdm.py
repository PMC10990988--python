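"""Representational dissimilarity matrices (RDMs) and pair-vector utilities.

An RDM stores pairwise dissimilarities between labelled items as a symmetric
matrix with a zero diagonal.  Throughout the package the matrix is
interchangeably handled as its upper-triangle vectorization in row-major
order (pairs (i, j) with i < j), which is the canonical layout for model
comparison and factorization.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

__all__ = ["RDM", "triu_pairs", "pair_index", "n_pairs"]

#: maximum tolerated asymmetry / diagonal magnitude before an input is rejected
SYMMETRY_TOL = 1e-9


def n_pairs(n_items: int) -> int:
    """Number of unordered item pairs, n(n-1)/2."""
    return n_items * (n_items - 1) // 2


def triu_pairs(n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle in row-major order."""
    return np.triu_indices(n_items, k=1)


def pair_index(n_items: int, i: int, j: int) -> int:
    """Position of pair (i, j), i < j, in the row-major upper-triangle vector."""
    if not 0 <= i < j < n_items:
        raise ValueError(f"need 0 <= i < j < n_items, got ({i}, {j})")
    return i * (2 * n_items - i - 1) // 2 + (j - i - 1)


@dataclasses.dataclass
class RDM:
    """A symmetric, zero-diagonal dissimilarity matrix with item labels.

    Parameters
    ----------
    labels
        Item identifiers, one per row/column.
    values
        Square array of pairwise dissimilarities.  Must be symmetric within
        ``1e-9`` and have a (near-)zero diagonal; both are enforced exactly
        after validation.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM values must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate item labels")
        finite = np.isfinite(v)
        asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance (max |A-A.T| = {asym:g})")
        if v.size and np.nanmax(np.abs(np.diag(v))) > SYMMETRY_TOL:
            raise ValueError("RDM diagonal must be zero")
        # canonicalize: exact symmetry, exact zero diagonal
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if finite.all() and (v < -SYMMETRY_TOL).any():
            raise ValueError("RDM entries must be nonnegative")
        self.values = v

    # -- basic geometry -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def utv(self) -> np.ndarray:
        """Row-major upper-triangle vectorization (copy)."""
        i, j = triu_pairs(self.n)
        return self.values[i, j].copy()

    @classmethod
    def from_utv(cls, labels: Sequence[str], vec: np.ndarray) -> "RDM":
        """Rebuild a square RDM from its upper-triangle vector."""
        labels = list(labels)
        n = len(labels)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (n_pairs(n),):
            raise ValueError(
                f"expected {n_pairs(n)} pair values for {n} items, got {vec.shape}"
            )
        m = np.zeros((n, n))
        i, j = triu_pairs(n)
        m[i, j] = vec
        m[j, i] = vec
        return cls(labels, m)

    def pair_labels(self) -> list[tuple[str, str]]:
        i, j = triu_pairs(self.n)
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    # -- transforms ------------------------------------------------------

    def normalized(self) -> "RDM":
        """Scale so the upper-triangle vector has unit standard deviation."""
        sd = float(np.std(self.utv))
        if sd <= 0.0:
            raise ValueError("cannot normalize a constant RDM (zero SD)")
        return RDM(list(self.labels), self.values / sd)

    def sub_rdm(self, subset: Iterable[str]) -> "RDM":
        """Restriction to a subset of items, in the given order."""
        subset = [str(s) for s in subset]
        pos = {lab: k for k, lab in enumerate(self.labels)}
        try:
            idx = np.array([pos[s] for s in subset], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown item label {exc.args[0]!r}") from None
        return RDM(subset, self.values[np.ix_(idx, idx)])

    def copy(self) -> "RDM":
        return RDM(list(self.labels), self.values.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RDM):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)
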