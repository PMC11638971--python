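"""Cross-modal distances, SVD projection, and minimum-cost linear assignment.

The matching step solves

    minimize <Pi, D>   over 0/1 matrices Pi with row/column sums <= 1
                       and exactly n_min = min(n_y, n_z) ones,

i.e. a rectangular linear assignment problem, via the shortest augmenting
path solver in :func:`scipy.optimize.linear_sum_assignment`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import LEVEL_METACELL, PROV_INITIAL, MatchTable
from .exceptions import DataError, ParameterError
from .graph import pairwise_distances

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Dense cross-modal distance matrix with its metric tag."""

    values: np.ndarray  # n_y x n_z
    metric: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise DataError("distance matrix contains non-finite entries")


def svd_project(a: np.ndarray, r: int) -> np.ndarray:
    """Scores ``U_r @ diag(S_r)`` of the rank-r SVD of the column-centered matrix.

    Sign convention: the largest-magnitude element of each right singular
    vector is made positive, so results are reproducible across runs.
    """
    a = np.asarray(a, dtype=np.float64)
    n, m = a.shape
    if not 1 <= r <= min(n, m):
        raise ParameterError(f"r={r} must be in [1, min(n, m)={min(n, m)}]")
    centered = a - a.mean(axis=0, keepdims=True)
    u, s, vh = np.linalg.svd(centered, full_matrices=False)
    u, s, vh = u[:, :r], s[:r], vh[:r]
    for j in range(r):
        i = np.argmax(np.abs(vh[j]))
        if vh[j, i] < 0:
            vh[j] *= -1.0
            u[:, j] *= -1.0
    return u * s


def svd_denoise(a: np.ndarray, r: int) -> np.ndarray:
    """Project rows onto the leading rank-r singular subspace.

    Unlike :func:`svd_project`, the result stays in the original column
    coordinate system (truncated-SVD reconstruction plus the column means),
    so denoised matrices from two modalities with corresponding columns
    remain directly comparable.  ``r = rank(A)`` returns the input.
    """
    a = np.asarray(a, dtype=np.float64)
    n, m = a.shape
    if not 1 <= r <= min(n, m):
        raise ParameterError(f"r={r} must be in [1, min(n, m)={min(n, m)}]")
    if r == min(n, m):
        return a.copy()
    mean = a.mean(axis=0, keepdims=True)
    u, s, vh = np.linalg.svd(a - mean, full_matrices=False)
    return (u[:, :r] * s[:r]) @ vh[:r] + mean


def cross_distance(a: np.ndarray, b: np.ndarray, metric: str = "correlation") -> DistanceMatrix:
    """Distance between every row of ``a`` and every row of ``b``."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ParameterError(
            f"column counts differ: {a.shape[1]} vs {b.shape[1]}"
        )
    if metric == "correlation" and a.shape[1] < 2:
        raise ParameterError("correlation distance undefined for fewer than 2 columns")
    return DistanceMatrix(values=pairwise_distances(a, b, metric), metric=metric)


def linear_assignment(d: DistanceMatrix | np.ndarray) -> MatchTable:
    """Minimum-cost assignment of exactly ``min(n_y, n_z)`` disjoint pairs."""
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=np.float64)
    if values.size == 0:
        raise DataError("cannot solve assignment on an empty distance matrix")
    rows, cols = linear_sum_assignment(values)
    table = MatchTable(
        rows, cols, values[rows, cols], provenance=PROV_INITIAL, level=LEVEL_METACELL
    )
    logger.debug("assignment: %d pairs, objective %.6g", len(table), table.objective)
    return table


def initial_match(
    y_linked: np.ndarray,
    z_linked: np.ndarray,
    svd_y: int | None = None,
    svd_z: int | None = None,
    metric: str = "correlation",
) -> MatchTable:
    """Initial pivots from smoothed linked features.

    Each side is denoised by projection onto its own leading singular
    subspace; because the projection keeps the shared linked-feature
    coordinates (see :func:`svd_denoise`), the cross-modal distance matrix
    is computed directly on the denoised rows and solved by assignment.
    """
    if y_linked.shape[1] != z_linked.shape[1]:
        raise ParameterError("linked-feature matrices must share their columns")
    s = y_linked.shape[1]
    sy = min(svd_y or min(30, s), y_linked.shape[0], s)
    sz = min(svd_z or min(30, s), z_linked.shape[0], s)
    ys = svd_denoise(y_linked, sy)
    zs = svd_denoise(z_linked, sz)
    d = cross_distance(ys, zs, metric)
    return linear_assignment(d)


def batched_match(
    y_linked: np.ndarray,
    z_linked: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
    svd_y: int | None = None,
    svd_z: int | None = None,
    metric: str = "correlation",
) -> MatchTable:
    """Assignment at scale: partition the larger side into random batches.

    Each batch is matched against the full smaller side independently and
    the pair lists are concatenated; a smaller-side row may therefore appear
    in several pairs, to be resolved by downstream filtering/pruning.
    """
    if batch_size < 2:
        raise ParameterError(f"batch_size={batch_size} must be >= 2")
    n_y, n_z = y_linked.shape[0], z_linked.shape[0]
    larger_is_y = n_y >= n_z
    n_large = n_y if larger_is_y else n_z
    if batch_size >= n_large:
        return initial_match(y_linked, z_linked, svd_y, svd_z, metric)
    perm = rng.permutation(n_large)
    n_batches = int(np.ceil(n_large / batch_size))
    tables = []
    for chunk in np.array_split(perm, n_batches):
        chunk = np.sort(chunk)
        if larger_is_y:
            sub = initial_match(y_linked[chunk], z_linked, svd_y, svd_z, metric)
            tables.append(
                MatchTable(chunk[sub.idx_a], sub.idx_b, sub.distance,
                           provenance=PROV_INITIAL, level=LEVEL_METACELL)
            )
        else:
            sub = initial_match(y_linked, z_linked[chunk], svd_y, svd_z, metric)
            tables.append(
                MatchTable(sub.idx_a, chunk[sub.idx_b], sub.distance,
                           provenance=PROV_INITIAL, level=LEVEL_METACELL)
            )
    logger.info("batched matching: %d batches of <= %d", n_batches, batch_size)
    return MatchTable.concat(tables)
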