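"""Nodal graph metrics and their integration over the sparsity grid.

Three per-node metrics are computed on each binarized graph: degree
centrality (edge count), betweenness centrality (unnormalized Brandes
form: sum over unordered pairs of the fraction of shortest paths through
the node), and nodal efficiency (mean inverse shortest-path length to all
other nodes, with 1/inf = 0 for unreachable pairs).  Each metric curve
across the sparsity grid is summarized by its trapezoidal area under the
curve (AUC), a threshold-free nodal statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import (
    BinaryGraph,
    edge_count_at_sparsity,
    edge_ranking,
    sparsity_grid,
)

__all__ = [
    "NodalMetricCurve",
    "METRIC_NAMES",
    "degree_centrality",
    "betweenness_centrality",
    "nodal_efficiency",
    "auc_over_sparsity",
    "metric_pipeline",
]

METRIC_NAMES = ("degree", "betweenness", "efficiency")


@dataclass
class NodalMetricCurve:
    """Per-node values of one metric across the sparsity grid, plus AUC."""

    metric_name: str
    values: np.ndarray  # node x sparsity
    grid: np.ndarray
    auc: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        self.auc = np.asarray(self.auc, dtype=float)
        if self.values.shape[1] != self.grid.size:
            raise ValueError("values columns must match the sparsity grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")
        if not np.isfinite(self.auc).all():
            raise ValueError("AUC contains non-finite values")


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Unnormalized degree: number of edges incident to each node."""
    return g.adjacency.sum(axis=1).astype(float)


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Unnormalized betweenness over unordered node pairs (Brandes)."""
    return _betweenness_from_adjacency(g.adjacency)


def _betweenness_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(np.triu(adjacency, 1))
    graph = ig.Graph(
        n=adjacency.shape[0], edges=list(zip(rows.tolist(), cols.tolist()))
    )
    return np.asarray(graph.betweenness(directed=False), dtype=float)


def nodal_efficiency(g: BinaryGraph) -> np.ndarray:
    """E_i = mean over j != i of 1/d_ij, with unreachable pairs contributing 0."""
    return _efficiency_from_adjacency(g.adjacency)


def _efficiency_from_adjacency(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    if n < 2:
        return np.zeros(n)
    d = shortest_path(csr_matrix(adjacency), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def auc_over_sparsity(values: np.ndarray, grid) -> np.ndarray:
    """Trapezoidal integral of per-node metric values against sparsity.

    ``values`` has nodes on the first axis and grid points on the last.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("sparsity grid must have at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != grid.size:
        raise ValueError("last axis of values must match the grid")
    return np.trapezoid(values, grid, axis=-1)


def metric_pipeline(
    z_matrix: np.ndarray,
    grid: list[float] | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, NodalMetricCurve]:
    """Binarize a weighted matrix at every grid sparsity and compute all
    requested nodal metrics and their AUCs.

    The thresholded graphs are nested, so the ranked edge list is computed
    once and adjacency grown incrementally across the grid.
    """
    z = np.asarray(z_matrix, dtype=float)
    n = z.shape[0]
    if grid is None:
        grid = sparsity_grid()
    grid_arr = np.asarray(grid, dtype=float)
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")

    rows, cols = edge_ranking(z)
    out = {m: np.zeros((n, grid_arr.size)) for m in metrics}
    A = np.zeros((n, n), dtype=np.int8)
    prev = 0
    for gi, s in enumerate(grid_arr):
        E = edge_count_at_sparsity(float(s), n)
        if E == 0:
            raise ValueError(f"sparsity {s} rounds to zero edges for N={n}")
        r, c = rows[prev:E], cols[prev:E]
        A[r, c] = 1
        A[c, r] = 1
        prev = E
        if "degree" in out:
            out["degree"][:, gi] = A.sum(axis=1)
        if "betweenness" in out:
            out["betweenness"][:, gi] = _betweenness_from_adjacency(A)
        if "efficiency" in out:
            out["efficiency"][:, gi] = _efficiency_from_adjacency(A)

    return {
        m: NodalMetricCurve(
            metric_name=m,
            values=v,
            grid=grid_arr,
            auc=auc_over_sparsity(v, grid_arr),
        )
        for m, v in out.items()
    }
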