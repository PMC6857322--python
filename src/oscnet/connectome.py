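"""Band-resolved functional connectome construction and sparsity thresholding.

Edges are Pearson correlations between ROI time courses, Fisher
r-to-z transformed.  Each weighted matrix is binarized over a grid of
sparsity values (fraction of realized edges among N(N-1)/2 possible);
at sparsity S the round(S * N(N-1)/2) strongest positive-signed edges are
kept, so graphs at increasing sparsity are nested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TimeSeriesMatrix

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "correlation_matrix",
    "fisher_z",
    "binarize_at_sparsity",
    "sparsity_grid",
    "edge_ranking",
    "edge_count_at_sparsity",
]

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity over the network nodes."""

    z_values: np.ndarray
    r_values: np.ndarray
    band: str = "broadband"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.r_values = np.asarray(self.r_values, dtype=float)
        for M in (self.z_values, self.r_values):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError("connectivity matrices must be square")
            if not np.allclose(M, M.T, atol=1e-12):
                raise ValueError("connectivity matrices must be symmetric")
        if not np.isfinite(self.z_values).all():
            raise ValueError("z matrix contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.z_values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency at a fixed sparsity (zero diagonal)."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = A.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time courses."""
    X = ts.values
    if X.shape[1] < 3:
        raise ValueError("correlation needs at least 3 time points")
    sd = X.std(axis=1)
    # constant rows can carry float residue from the mean subtraction
    dead = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=1)))
    if dead.size:
        names = (
            [ts.roi_labels[i] for i in dead] if ts.roi_labels is not None else list(dead)
        )
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(X)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = fisher_z(r)
    return ConnectivityMatrix(z_values=z, r_values=r, band=ts.band)


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher r-to-z (arctanh) elementwise off-diagonal, diagonal set to 0.

    r is clipped to +/-(1 - 1e-7) first so that perfectly correlated pairs
    stay finite.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        z = z.copy()
        np.fill_diagonal(z, 0.0)
    return z


def edge_count_at_sparsity(sparsity: float, n_nodes: int) -> int:
    """round(S * N(N-1)/2) with half-away-from-zero rounding."""
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * n_pairs + 0.5))


def edge_ranking(z_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangular edges ordered by descending signed weight.

    Ties are broken by lexicographic (i, j) so rankings are reproducible.
    Returns (rows, cols) index arrays; the top-E prefix of this ordering is
    the edge set at any sparsity, which makes the thresholded graphs nested.
    """
    z = np.asarray(z_matrix, dtype=float)
    iu, ju = np.triu_indices(z.shape[0], 1)
    w = z[iu, ju]
    # lexsort uses the last key as primary: sort by (-w, i, j)
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_sparsity(z_matrix: np.ndarray, sparsity: float) -> BinaryGraph:
    """Keep the strongest edges (signed weights) at the given sparsity."""
    z = np.asarray(z_matrix, dtype=float)
    n = z.shape[0]
    E = edge_count_at_sparsity(sparsity, n)
    if E == 0:
        raise ValueError(f"sparsity {sparsity} rounds to zero edges for N={n}")
    rows, cols = edge_ranking(z)
    A = np.zeros((n, n), dtype=np.int8)
    A[rows[:E], cols[:E]] = 1
    A |= A.T
    return BinaryGraph(adjacency=A, sparsity=sparsity)


def sparsity_grid() -> list[float]:
    """The canonical sparsity grid: 5% to 50% in steps of 5%."""
    return [round(0.05 * k, 2) for k in range(1, 11)]
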