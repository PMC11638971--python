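"""Self-inclusive nearest-neighbor graphs and the fuzzy smoothing operator.

Fuzzy smoothing shrinks each row of a matrix towards the average over that
row's graph neighborhood:

    S(A; w) = w * A + (1 - w) * K^{-1} G A

where ``G`` is a binary k-NN adjacency whose diagonal is all ones and ``K``
is the diagonal matrix of row degrees.  ``w = 1`` is the identity; ``w = 0``
replaces every row by its neighborhood mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .exceptions import ParameterError


@dataclass
class NeighborGraph:
    """Binary self-inclusive k-NN adjacency with per-row degrees."""

    adjacency: sparse.csr_matrix  # n x n, row i has degrees[i] ones, diag all ones
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def pairwise_distances(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs row distances; correlation distance is 1 - Pearson in [0, 2].

    Rows with zero variance have undefined correlation with anything; such
    entries are set to 1 (treated as uncorrelated).
    """
    if metric == "correlation":
        d = cdist(a, b, metric="correlation")
        # constant rows yield NaN; define them as uncorrelated
        np.nan_to_num(d, nan=1.0, copy=False)
        np.clip(d, 0.0, 2.0, out=d)
        return d
    if metric == "euclidean":
        return cdist(a, b, metric="euclidean")
    raise ParameterError(f"unknown distance metric {metric!r}")


def build_nn_graph(matrix: np.ndarray, k: int, metric: str = "correlation") -> NeighborGraph:
    """Connect each row to its ``k`` nearest rows (itself always included).

    Ties are broken towards the lower row index.  The graph is directed
    (asymmetric): no symmetrization is applied, as the smoothing operator
    normalizes by row degree.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of rows n={n}")
    if k < 1:
        raise ParameterError(f"k={k} must be >= 1")
    d = pairwise_distances(matrix, matrix, metric)
    # force self-inclusion regardless of metric degeneracies
    np.fill_diagonal(d, -np.inf)
    # stable sort => ties broken by lower index
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    adjacency = sparse.csr_matrix(
        (np.ones(n * k), (rows, order.ravel())), shape=(n, n)
    )
    degrees = np.full(n, k, dtype=np.int64)
    return NeighborGraph(adjacency=adjacency, degrees=degrees)


def fuzzy_smooth(a: np.ndarray, graph: NeighborGraph, w: float) -> np.ndarray:
    """Apply S(A; w) = w A + (1 - w) K^{-1} G A."""
    a = np.asarray(a, dtype=np.float64)
    if a.shape[0] != graph.n:
        raise ParameterError(
            f"matrix has {a.shape[0]} rows but graph has {graph.n} nodes"
        )
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"smoothing weight w={w} must be in [0, 1]")
    if w == 1.0:
        return a.copy()
    local_mean = graph.adjacency @ a / graph.degrees[:, None]
    return w * a + (1.0 - w) * local_mean
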