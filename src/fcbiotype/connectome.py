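"""Per-subject connectivity matrices and their edge-vector form.

Connectivity is stored on the Fisher-z scale (arctanh of the BOLD
correlation), which is variance-stabilizing and approximately Gaussian.
Matrices are symmetric with a zero diagonal; the analysis operates on
the vectorized strict upper triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import n_edges
from .errors import DimensionError, FormatError

SYMMETRY_ATOL = 1e-10


def fisher_z(r, clamp: float | None = None):
    """Fisher z-transform arctanh(r) of a correlation coefficient.

    Parameters
    ----------
    r : float or array-like
        Correlation(s) with |r| < 1.
    clamp : float, optional
        If given, values with |r| >= 1 are clamped to 1 - clamp before
        transforming; otherwise they raise :class:`FormatError`.
    """
    r = np.asarray(r, dtype=float)
    if clamp is not None:
        r = np.clip(r, -1.0 + clamp, 1.0 - clamp)
    elif np.any(np.abs(r) >= 1.0):
        raise FormatError("|r| >= 1 cannot be Fisher-transformed; pass clamp=eps to clip")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def edge_index(P: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column ROI indices (0-based) of edge e = 0..P(P-1)/2-1.

    Ordering is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,P-1), (1,2), ...
    """
    return np.triu_indices(P, k=1)


def vectorize_upper(matrix: np.ndarray, atol: float = SYMMETRY_ATOL) -> np.ndarray:
    """Vectorize a symmetric matrix into its strict upper triangle.

    Raises :class:`FormatError` if the matrix is asymmetric beyond
    ``atol``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DimensionError(f"expected a square matrix, got shape {m.shape}")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > atol:
        raise FormatError(f"matrix asymmetric beyond tolerance: max |A - A.T| = {asym:g}")
    iu, ju = edge_index(m.shape[0])
    return m[iu, ju].copy()


def devectorize(edges: np.ndarray, P: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix, zero diagonal."""
    edges = np.asarray(edges)
    if edges.shape[-1] != n_edges(P):
        raise DimensionError(
            f"edge vector length {edges.shape[-1]} does not match P={P} "
            f"(expected {n_edges(P)})"
        )
    m = np.zeros(edges.shape[:-1] + (P, P), dtype=edges.dtype)
    iu, ju = edge_index(P)
    m[..., iu, ju] = edges
    m[..., ju, iu] = edges
    return m


@dataclass
class ConnectomeStack:
    """Edge table for a set of subjects: subjects x P(P-1)/2 Fisher-z values.

    Attributes
    ----------
    subject_ids : list of str
    edges : ndarray, shape (n_subjects, n_edges)
        Vectorized strict upper triangles, row-major (i < j) ordering.
    P : int
        Number of ROIs.
    """

    subject_ids: list[str]
    edges: np.ndarray
    P: int = field(default=0)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.subject_ids) != len(set(self.subject_ids)):
            raise FormatError("duplicate subject ids in connectome stack")
        if self.edges.ndim != 2 or self.edges.shape[0] != len(self.subject_ids):
            raise DimensionError(
                f"edges shape {self.edges.shape} does not match "
                f"{len(self.subject_ids)} subjects"
            )
        if self.P == 0:
            # infer P from E = P(P-1)/2
            E = self.edges.shape[1]
            self.P = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
        if n_edges(self.P) != self.edges.shape[1]:
            raise DimensionError(
                f"edge count {self.edges.shape[1]} inconsistent with P={self.P}"
            )

    @classmethod
    def from_matrices(
        cls, subject_ids: list[str], matrices: np.ndarray, atol: float = SYMMETRY_ATOL
    ) -> "ConnectomeStack":
        """Build from per-subject symmetric P x P matrices."""
        matrices = np.asarray(matrices, dtype=float)
        rows = [vectorize_upper(m, atol=atol) for m in matrices]
        return cls(list(subject_ids), np.asarray(rows), P=matrices.shape[-1])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def matrix(self, subject_id: str) -> np.ndarray:
        """Reconstruct one subject's symmetric matrix (zero diagonal)."""
        i = self.subject_ids.index(subject_id)
        return devectorize(self.edges[i], self.P)

    def matrices(self) -> np.ndarray:
        """All subjects' matrices, shape (n_subjects, P, P)."""
        return devectorize(self.edges, self.P)

    def subset(self, indices) -> "ConnectomeStack":
        indices = np.asarray(indices)
        return ConnectomeStack(
            [self.subject_ids[i] for i in indices], self.edges[indices], P=self.P
        )
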