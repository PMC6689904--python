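"""Directed weighted dyadic matrices and their vector form.

The unit of analysis throughout is the ordered dyad (A, B), A != B.  An
n-node study yields n*(n-1) ordered dyads; for the 12 focal animals of a
typical chimpanzee study this is 132.  Matrices are stored dense with a
structurally-zero diagonal, and every regression consumes the off-diagonal
entries flattened in a fixed row-major dyad order so that the same cell of
every matrix refers to the same ordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DyadMatrix",
    "offdiag_indices",
    "vectorize",
    "devectorize",
]


def offdiag_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the n*(n-1) off-diagonal cells, row-major."""
    mask = ~np.eye(n, dtype=bool)
    return np.nonzero(mask)


@dataclass
class DyadMatrix:
    """A labelled n x n dyadic measure (rate, duration, or similarity).

    Parameters
    ----------
    labels
        Node identifiers, in the row/column order of ``values``.
    values
        Square matrix; the diagonal must be identically zero (an animal
        holds no dyadic tie with itself).
    name
        Measure label, e.g. ``"proximity"`` or ``"persistence"``.
    directed
        Whether values[i, j] and values[j, i] are distinct measures.
    """

    labels: list[str]
    values: np.ndarray
    name: str = ""
    directed: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix {self.name!r}: values shape {self.values.shape} "
                f"does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError(f"matrix {self.name!r}: duplicate node labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"matrix {self.name!r}: non-finite values")
        if n and np.any(np.diag(self.values) != 0):
            raise ValueError(f"matrix {self.name!r}: nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1)

    def vector(self, mask: np.ndarray | None = None) -> np.ndarray:
        return vectorize(self, mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long format (from, to, value) over ordered off-diagonal dyads."""
        i, j = offdiag_indices(self.n)
        lab = np.asarray(self.labels)
        return pd.DataFrame(
            {"from": lab[i], "to": lab[j], "value": self.values[i, j]}
        )

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, rtol=0))

    def aligned_to(self, labels: list[str]) -> "DyadMatrix":
        """Reindex rows and columns to a reference label order."""
        if set(labels) != set(self.labels):
            raise ValueError(
                f"matrix {self.name!r}: label set differs from reference"
            )
        idx = [self.labels.index(l) for l in labels]
        return DyadMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.name, self.directed
        )


def vectorize(matrix: DyadMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Off-diagonal entries in fixed row-major dyad order.

    ``mask``, if given, is a boolean n x n matrix marking dyads to *keep*;
    its diagonal is ignored.  The same mask must be applied to every matrix
    entering one model so the dyad vectors stay aligned.
    """
    n = matrix.n
    i, j = offdiag_indices(n)
    v = matrix.values[i, j]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, n):
            raise ValueError(
                f"mask shape {mask.shape} does not match matrix order {n}"
            )
        v = v[mask[i, j]]
    return v


def devectorize(
    vec: np.ndarray, labels: list[str], name: str = "", directed: bool = True
) -> DyadMatrix:
    """Inverse of :func:`vectorize` for unmasked vectors (zero diagonal)."""
    n = len(labels)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1),):
        raise ValueError(
            f"vector length {vec.size} does not match {n * (n - 1)} dyads"
        )
    out = np.zeros((n, n))
    i, j = offdiag_indices(n)
    out[i, j] = vec
    return DyadMatrix(list(labels), out, name, directed)
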