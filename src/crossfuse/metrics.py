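"""Evaluation criteria for cross-modal integration.

Quantities computed here assess two things: matching quality (do matched
cells share a cell type? is the true partner nearby in the embedding?) and
embedding quality (are modalities mixed while cell types stay separated?).

FOSCTTM -- the fraction of opposite-modality cells lying closer to a cell
than its true match, averaged over cells and both directions -- is 0 for a
perfect alignment.  FOSKNN is the fraction of cells whose true match lies
among their k nearest opposite-modality neighbors.  Both require datasets
with a known single-cell-level pairing, rows aligned so that row i in both
embeddings is the same cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .datatypes import LEVEL_SINGLECELL, MatchTable
from .exceptions import DataError, ParameterError
from .graph import pairwise_distances


@dataclass
class EvaluationReport:
    """Bundle of the evaluation criteria for one integration run."""

    accuracy_by_level: dict[str, float] = field(default_factory=dict)
    foscttm: float | None = None
    fosknn: dict[int, float] = field(default_factory=dict)
    slt_f1: float | None = None
    ari_f1: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy_by_level": self.accuracy_by_level,
            "foscttm": self.foscttm,
            "fosknn": {str(k): v for k, v in self.fosknn.items()},
            "slt_f1": self.slt_f1,
            "ari_f1": self.ari_f1,
        }


def matching_accuracy(
    table: MatchTable, labels_y: list[str] | np.ndarray, labels_z: list[str] | np.ndarray
) -> float:
    """Fraction of matched pairs whose two cells carry the same annotation."""
    if len(table) == 0:
        raise DataError("matching accuracy undefined for an empty pair list")
    labels_y = np.asarray(labels_y, dtype=object)
    labels_z = np.asarray(labels_z, dtype=object)
    if table.idx_a.max() >= len(labels_y):
        raise DataError(f"missing label for modality-1 index {int(table.idx_a.max())}")
    if table.idx_b.max() >= len(labels_z):
        raise DataError(f"missing label for modality-2 index {int(table.idx_b.max())}")
    return float(np.mean(labels_y[table.idx_a] == labels_z[table.idx_b]))


def knn_match_from_embedding(
    emb_y: np.ndarray, emb_z: np.ndarray, direction: str = "y_to_z"
) -> MatchTable:
    """Pair each query cell with its opposite-modality 1-NN by correlation distance."""
    emb_y = np.asarray(emb_y, dtype=np.float64)
    emb_z = np.asarray(emb_z, dtype=np.float64)
    if emb_y.shape[1] != emb_z.shape[1]:
        raise ParameterError("embeddings must share their dimension")
    if emb_y.shape[1] < 2:
        raise ParameterError("correlation distance needs >= 2 embedding dimensions")
    if direction == "y_to_z":
        d = pairwise_distances(emb_y, emb_z, "correlation")
        nn = np.argmin(d, axis=1)
        idx_a, idx_b = np.arange(len(emb_y)), nn
        dist = d[idx_a, nn]
    elif direction == "z_to_y":
        d = pairwise_distances(emb_z, emb_y, "correlation")
        nn = np.argmin(d, axis=1)
        idx_a, idx_b = nn, np.arange(len(emb_z))
        dist = d[np.arange(len(emb_z)), nn]
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    return MatchTable(idx_a, idx_b, dist, provenance="initial", level=LEVEL_SINGLECELL)


def _check_paired(emb_y: np.ndarray, emb_z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    emb_y = np.asarray(emb_y, dtype=np.float64)
    emb_z = np.asarray(emb_z, dtype=np.float64)
    if emb_y.shape[0] != emb_z.shape[0]:
        raise ParameterError(
            "ground-truth single-cell-level pairing required: embeddings must "
            f"have equal row counts, got {emb_y.shape[0]} and {emb_z.shape[0]}"
        )
    return emb_y, emb_z


def foscttm(emb_y: np.ndarray, emb_z: np.ndarray, metric: str = "euclidean") -> float:
    """Average fraction of opposite-modality cells closer than the true match.

    FOSCTTM = (1/2N) * (sum_i n_y^(i)/N + sum_i n_z^(i)/N), where n_y^(i)
    counts cells j with d(y_i, z_j) < d(y_i, z_i).
    """
    emb_y, emb_z = _check_paired(emb_y, emb_z)
    n = emb_y.shape[0]
    d = pairwise_distances(emb_y, emb_z, metric)
    true = np.diag(d)
    n_y = np.sum(d < true[:, None], axis=1)   # per y_i over z_j
    n_z = np.sum(d < true[None, :], axis=0)   # per z_i over y_j
    return float((n_y.sum() / n + n_z.sum() / n) / (2 * n))


def fosknn(emb_y: np.ndarray, emb_z: np.ndarray, k: int, metric: str = "euclidean") -> float:
    """Fraction of cells whose true match is within their k nearest neighbors."""
    emb_y, emb_z = _check_paired(emb_y, emb_z)
    n = emb_y.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} must be in [1, N={n}]")
    d = pairwise_distances(emb_y, emb_z, metric)
    true = np.diag(d)
    # rank of the true match among each row's / column's distances
    rank_y = np.sum(d < true[:, None], axis=1)
    rank_z = np.sum(d < true[None, :], axis=0)
    return float((np.mean(rank_y < k) + np.mean(rank_z < k)) / 2)


def _normalized_silhouette(emb: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels.tolist())) < 2:
        raise ParameterError("silhouette undefined with a single label")
    return (silhouette_score(emb, labels) + 1.0) / 2.0


def _f1(a: float, b: float) -> float:
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def silhouette_f1(
    emb_joint: np.ndarray,
    modality_labels: np.ndarray | list,
    celltype_labels: np.ndarray | list,
) -> float:
    """Harmonic mean of modality mixing and cell-type separation.

    slt_mix = 1 - normalized silhouette on modality labels (higher = better
    mixed); slt_clust = normalized silhouette on cell-type labels (higher =
    better separated); silhouettes are mapped from [-1, 1] to [0, 1].
    """
    emb_joint = np.asarray(emb_joint, dtype=np.float64)
    modality_labels = np.asarray(modality_labels)
    celltype_labels = np.asarray(celltype_labels)
    slt_mix = 1.0 - _normalized_silhouette(emb_joint, modality_labels)
    slt_clust = _normalized_silhouette(emb_joint, celltype_labels)
    return _f1(np.clip(slt_mix, 0, 1), np.clip(slt_clust, 0, 1))


def ari_f1(
    emb_joint: np.ndarray,
    modality_labels: np.ndarray | list,
    celltype_labels: np.ndarray | list,
    n_clusters: int | None = None,
    seed: int = 0,
) -> float:
    """Like silhouette F1 but with the adjusted Rand index of a k-means clustering.

    The pooled embedding is clustered with k = number of cell types;
    ari_clust = ARI(clusters, cell types) and ari_mix = 1 - |ARI(clusters,
    modality)|, both clipped to [0, 1].
    """
    emb_joint = np.asarray(emb_joint, dtype=np.float64)
    modality_labels = np.asarray(modality_labels)
    celltype_labels = np.asarray(celltype_labels)
    types = sorted(set(celltype_labels.tolist()))
    if len(types) < 2:
        raise ParameterError("ARI F1 undefined with a single cell type")
    if len(set(modality_labels.tolist())) < 2:
        raise ParameterError("ARI F1 requires both modalities present")
    k = n_clusters or len(types)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb_joint)
    ari_clust = float(np.clip(adjusted_rand_score(celltype_labels, km), 0, 1))
    ari_mix = float(np.clip(1.0 - abs(adjusted_rand_score(modality_labels, km)), 0, 1))
    return _f1(ari_mix, ari_clust)


def evaluate_integration(
    emb_y: np.ndarray,
    emb_z: np.ndarray,
    matching: MatchTable | None = None,
    labels_y: np.ndarray | list | None = None,
    labels_z: np.ndarray | list | None = None,
    paired: bool = False,
    ks: tuple[int, ...] = (1, 5, 10),
    seed: int = 0,
    n_dims: int | None = None,
) -> EvaluationReport:
    """Convenience wrapper computing every applicable criterion.

    ``n_dims`` restricts all embedding-based metrics to the leading
    components (benchmarks conventionally use the first 15).
    """
    if n_dims is not None:
        emb_y = np.asarray(emb_y)[:, :n_dims]
        emb_z = np.asarray(emb_z)[:, :n_dims]
    report = EvaluationReport()
    if matching is not None and labels_y is not None and labels_z is not None:
        level = str(matching.level[0]) if len(matching) else LEVEL_SINGLECELL
        report.accuracy_by_level[level] = matching_accuracy(matching, labels_y, labels_z)
    if paired:
        report.foscttm = foscttm(emb_y, emb_z)
        n = np.asarray(emb_y).shape[0]
        report.fosknn = {k: fosknn(emb_y, emb_z, k) for k in ks if k <= n}
    if labels_y is not None and labels_z is not None:
        joint = np.vstack([emb_y, emb_z])
        modality = np.array(["mod1"] * len(emb_y) + ["mod2"] * len(emb_z))
        ct = np.concatenate([np.asarray(labels_y, dtype=object),
                             np.asarray(labels_z, dtype=object)])
        report.slt_f1 = silhouette_f1(joint, modality, ct)
        report.ari_f1 = ari_f1(joint, modality, ct, seed=seed)
    return report
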