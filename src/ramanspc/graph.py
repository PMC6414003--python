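"""Data matrix, distance matrix, neighbor graph and ferromagnetic couplings.

Spectra become columns of a data matrix (rows = Raman shifts).  Pairwise
Euclidean distances between columns feed a mutual-K-nearest-neighbor graph,
augmented with the minimum-spanning-tree edges so the graph is connected and
the low-temperature phase is a single ferromagnetic cluster.  Each edge
(i, j) carries the short-range coupling

    J_ij = (1 / K_hat) * exp(-d_ij^2 / (2 * d_bar^2)),

where d_bar is the mean distance over interacting neighbor pairs and K_hat
the average number of interacting neighbors per point (2|E|/n).  Couplings
of non-neighbor pairs are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .records import ConfigurationError, DegenerateSpectrumError, InputError, SpectrumRecord, same_grid


@dataclass
class SpectraMatrix:
    """Data matrix with rows = Raman shifts and columns = spectra."""

    values: np.ndarray  # (n_points, n_spectra)
    grid: np.ndarray
    column_labels: list[str | None] = field(default_factory=list)
    cohort_indices: list[int] = field(default_factory=list)

    @property
    def n_spectra(self) -> int:
        return self.values.shape[1]

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


@dataclass
class CouplingGraph:
    """Interacting-neighbor graph with distances and couplings.

    ``edges`` is an (m, 2) array of vertex pairs with i < j; ``d`` the edge
    distances; ``J`` the couplings (None until :func:`compute_couplings`).
    """

    n: int
    edges: np.ndarray
    d: np.ndarray
    d_bar: float
    k_hat: float
    J: np.ndarray | None = None

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def build_matrix(spectra: Sequence[SpectrumRecord]) -> SpectraMatrix:
    """Stack preprocessed spectra as columns, ordered by cohort index."""
    if not spectra:
        raise InputError("empty cohort")
    if not same_grid(spectra):
        raise InputError("spectra are not on a common grid")
    order = sorted(
        range(len(spectra)),
        key=lambda i: (
            spectra[i].cohort_index if spectra[i].cohort_index is not None else i + 1
        ),
    )
    cols = [spectra[i] for i in order]
    return SpectraMatrix(
        values=np.column_stack([s.intensities for s in cols]),
        grid=cols[0].wavenumbers,
        column_labels=[s.class_label for s in cols],
        cohort_indices=[
            s.cohort_index if s.cohort_index is not None else i + 1
            for i, s in enumerate(cols)
        ],
    )


def distance_matrix(matrix: SpectraMatrix | np.ndarray) -> np.ndarray:
    """Full symmetric matrix of pairwise Euclidean column distances."""
    values = matrix.values if isinstance(matrix, SpectraMatrix) else np.asarray(matrix)
    return squareform(pdist(values.T, metric="euclidean"))


def build_neighbor_graph(dist: np.ndarray, K: int = 10) -> CouplingGraph:
    """Mutual-K-nearest-neighbor graph augmented with MST edges.

    An edge (i, j) is kept iff i is among j's K nearest neighbors AND j is
    among i's; the minimum-spanning-tree edges of the distance matrix are
    added so the graph is connected.  Nearest-neighbor ties are broken by
    lower index (stable argsort), making the graph deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise InputError("distance matrix must be square")
    if not (1 <= K < n):
        raise ConfigurationError(f"K={K} out of range for n={n}")

    order = np.argsort(dist, axis=1, kind="stable")
    knn = np.zeros((n, n), dtype=bool)
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:K]
        knn[i, neighbors] = True
    mutual = knn & knn.T

    mst = minimum_spanning_tree(csr_matrix(dist)).toarray()
    mst_edges = mst > 0

    adj = mutual | mst_edges | mst_edges.T
    np.fill_diagonal(adj, False)
    ii, jj = np.where(np.triu(adj, 1))
    edges = np.column_stack([ii, jj])
    d = dist[ii, jj]
    d_bar = float(d.mean()) if d.size else 0.0
    k_hat = 2.0 * edges.shape[0] / n
    return CouplingGraph(n=n, edges=edges, d=d, d_bar=d_bar, k_hat=k_hat)


def compute_couplings(graph: CouplingGraph) -> CouplingGraph:
    """Populate J_ij = (1/K_hat) exp(-d_ij^2 / (2 d_bar^2)) on every edge."""
    if graph.d_bar <= 0:
        raise DegenerateSpectrumError(
            "mean neighbor distance is zero (all points coincide)"
        )
    if graph.k_hat <= 0:
        raise DegenerateSpectrumError("graph has no edges")
    J = np.exp(-0.5 * (graph.d / graph.d_bar) ** 2) / graph.k_hat
    return replace(graph, J=J)


def graph_from_spectra(
    spectra: Sequence[SpectrumRecord], K: int = 10
) -> tuple[SpectraMatrix, np.ndarray, CouplingGraph]:
    """Convenience chain: matrix -> distances -> coupled neighbor graph."""
    matrix = build_matrix(spectra)
    dist = distance_matrix(matrix)
    graph = compute_couplings(build_neighbor_graph(dist, K=K))
    return matrix, dist, graph


def write_edge_list(graph: CouplingGraph, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "i": graph.edges[:, 0],
            "j": graph.edges[:, 1],
            "d_ij": graph.d,
            "J_ij": graph.J if graph.J is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)
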