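"""Normalization, linked-feature matrices, and meta-cell aggregation.

Meta-cells are small within-modality clusters of similar cells whose
feature vectors are averaged into one row.  They denoise sparse
measurements and shrink the assignment problem.  Cluster granularity is
controlled by the *target mean size*: Leiden resolution is tuned by
bisection until the number of clusters lands in
``[N/(size+0.5), N/(size-0.5)]`` (or 20 bisection steps elapse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np

from .config import OFF
from .datatypes import LinkageMap, ModalityDataset
from .embed import pca_fit
from .exceptions import ConfigError, ParameterError
from .graph import build_nn_graph

logger = logging.getLogger(__name__)

NORM_SCHEMES = ("none", "log1p_total_scaled", "zscore_per_feature", "log1p_then_zscore")

#: library-size target for total-count scaling, the usual per-cell depth proxy
TOTAL_SCALE = 1e4


def _zscore(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)  # population SD
    out = matrix - mean
    nonzero = sd > 0
    out[:, nonzero] /= sd[nonzero]
    out[:, ~nonzero] = 0.0  # constant features carry no signal
    return out


def _log1p_total(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(matrix / totals * TOTAL_SCALE)


def normalize(dataset: ModalityDataset, scheme: str) -> ModalityDataset:
    """Return a transformed copy of the dataset under the named scheme."""
    if scheme not in NORM_SCHEMES:
        raise ConfigError(f"unknown normalization scheme {scheme!r}")
    m = dataset.matrix.copy()
    if scheme == "log1p_total_scaled":
        m = _log1p_total(m)
    elif scheme == "zscore_per_feature":
        m = _zscore(m)
    elif scheme == "log1p_then_zscore":
        m = _zscore(_log1p_total(m))
    return ModalityDataset(m, list(dataset.cell_ids), list(dataset.feature_ids),
                           None if dataset.cell_types is None else list(dataset.cell_types))


def make_linked_matrices(
    dataset_y: ModalityDataset,
    dataset_z: ModalityDataset,
    linkage: LinkageMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the two linked-feature matrices with matching column order."""
    cols_y = [dataset_y.feature_index(a) for a, _ in linkage.pairs]
    cols_z = [dataset_z.feature_index(b) for _, b in linkage.pairs]
    return dataset_y.matrix[:, cols_y].copy(), dataset_z.matrix[:, cols_z].copy()


@dataclass
class MetaCellMap:
    """Assignment of single cells to meta-cells plus averaged feature rows."""

    assignment: np.ndarray          # (N,) cluster index in [0, n_meta)
    n_meta: int
    all_feature_means: np.ndarray   # (n_meta, p)
    linked_feature_means: np.ndarray  # (n_meta, s)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_meta)

    def members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == m)


def _group_means(matrix: np.ndarray, assignment: np.ndarray, n_meta: int) -> np.ndarray:
    sums = np.zeros((n_meta, matrix.shape[1]))
    np.add.at(sums, assignment, matrix)
    counts = np.bincount(assignment, minlength=n_meta).astype(float)
    return sums / counts[:, None]


def _leiden_n_clusters(g: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def build_metacells(
    dataset: ModalityDataset,
    linked_matrix: np.ndarray,
    target_size: float | str,
    k_nn: int = 15,
    seed: int = 0,
    r_pca: int = 30,
    metric: str = "correlation",
) -> MetaCellMap:
    """Cluster cells into meta-cells of a target mean size and average rows.

    ``target_size`` of 1 (or ``"off"``) returns the identity map.  The k-NN
    graph is built on a PCA reduction of the all-feature matrix; Leiden
    resolution is then bisected until ``N / n_meta`` hits the target band.
    """
    n = dataset.n_cells
    if target_size == OFF or target_size == 1:
        return MetaCellMap(np.arange(n), n, dataset.matrix.copy(), linked_matrix.copy())
    if target_size < 1:
        raise ParameterError(f"target_size={target_size} must be >= 1 or 'off'")
    if k_nn >= n:
        raise ParameterError(f"k_nn={k_nn} must be smaller than the number of cells {n}")

    r = int(min(r_pca, dataset.n_features, n - 1))
    reduced = pca_fit(dataset.matrix, r).scores
    graph = build_nn_graph(reduced, k_nn, metric)
    adj = graph.adjacency.tocoo()
    mask = adj.row != adj.col  # drop self-loops for community detection
    g = igraph.Graph(
        n=n, edges=list(zip(adj.row[mask].tolist(), adj.col[mask].tolist())),
        directed=False,
    ).simplify()

    lo_n, hi_n = n / (target_size + 0.5), n / (target_size - 0.5)

    def n_meta_at(res: float) -> tuple[int, np.ndarray]:
        memb = _leiden_n_clusters(g, res, seed)
        return memb.max() + 1, memb

    # bracket the target band: n_meta grows with resolution
    res_lo, res_hi = 1e-4, 1.0
    k_lo, memb = n_meta_at(res_lo)
    k_hi, memb_hi = n_meta_at(res_hi)
    expand = 0
    while k_hi < lo_n and expand < 10:
        res_hi *= 4
        k_hi, memb_hi = n_meta_at(res_hi)
        expand += 1
    if k_hi >= lo_n:
        memb = memb_hi
    best = memb
    for _ in range(20):
        k_best = best.max() + 1
        if lo_n <= k_best <= hi_n:
            break
        mid = np.sqrt(res_lo * res_hi)
        k_mid, memb_mid = n_meta_at(mid)
        best = memb_mid
        if k_mid < lo_n:
            res_lo = mid
        elif k_mid > hi_n:
            res_hi = mid
        else:
            break
    n_meta = best.max() + 1
    logger.info("meta-cells: %d cells -> %d clusters (mean size %.2f)",
                n, n_meta, n / n_meta)
    return MetaCellMap(
        assignment=best,
        n_meta=n_meta,
        all_feature_means=_group_means(dataset.matrix, best, n_meta),
        linked_feature_means=_group_means(linked_matrix, best, n_meta),
    )
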