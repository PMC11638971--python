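"""Synthetic co-assayed multi-modality data with known ground truth.

The generator emulates the essential geometry of multiome-style benchmarks:
every cell has one latent state shared by all modalities, cells fall into
separated clusters, each modality observes the latent state through its own
random linear feature map plus noise, and a controllable subset of feature
pairs is *linked* across modalities with tunable cross-modal correlation
``rho`` (the linked z-side column is ``rho * standardized y-side signal +
sqrt(1 - rho^2) * independent noise``, so the realized correlation tracks
``rho`` analytically).  Rows are shuffled independently per modality and the
permutation is recorded as the masked ground-truth pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import LinkageMap, ModalityDataset
from .exceptions import DataError, ParameterError


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_cells: int = 1000
    n_clusters: int = 6
    latent_dim: int = 10
    p_y: int = 200
    p_z: int = 60
    p_w: int | None = None          # third modality; None = bimodal
    s_linked: int = 30
    linkage_rho: float = 0.7        # expected cross-modal correlation of linked pairs
    noise_sd_y: float = 0.3
    noise_sd_z: float = 0.3
    noise_sd_w: float = 0.3
    dropout_rate_z: float = 0.0     # multiplicative zeroing on the z modality
    #: between-cluster to within-cluster variance ratio; 8 gives well-separated
    #: but overlapping-tail clusters comparable to annotated cell types
    separation: float = 8.0
    missing_cluster_in: tuple[str, int] | None = None  # e.g. ("z", 3)
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_linked > min(self.p_y, self.p_z):
            raise ParameterError("s_linked exceeds a modality's feature count")
        if not 0.0 <= self.linkage_rho <= 1.0:
            raise ParameterError("linkage_rho must be in [0, 1]")
        if not 0.0 <= self.dropout_rate_z < 1.0:
            raise ParameterError("dropout_rate_z must be in [0, 1)")
        if self.n_clusters < 2:
            raise ParameterError("need at least 2 clusters")
        if self.missing_cluster_in is not None:
            mod, c = self.missing_cluster_in
            if mod not in ("y", "z", "w"):
                raise ParameterError("missing_cluster_in modality must be y, z or w")
            if not 0 <= c < self.n_clusters:
                raise ParameterError("missing cluster id out of range")
            if self.n_clusters - 1 < 2:
                raise DataError("cluster removal would leave fewer than 2 clusters")


@dataclass
class SyntheticTruth:
    """Masked ground truth for evaluation.

    ``pairing_yz[k] = (i, j)``: row i of the y matrix and row j of the z
    matrix are the same cell.  Cluster labels are per retained row of each
    modality, as strings, so they double as cell-type annotations.
    """

    pairing_yz: np.ndarray                  # (n_pairs, 2)
    pairing_zw: np.ndarray | None
    clusters_y: np.ndarray
    clusters_z: np.ndarray
    clusters_w: np.ndarray | None = None


@dataclass
class SyntheticData:
    dataset_y: ModalityDataset
    dataset_z: ModalityDataset
    dataset_w: ModalityDataset | None
    linkage_yz: LinkageMap
    linkage_zw: LinkageMap | None
    truth: SyntheticTruth
    spec: SyntheticSpec


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _linked_columns(signal: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Columns correlated at ~rho with the standardized source columns."""
    src = _standardize(signal)
    noise = rng.standard_normal(src.shape)
    return rho * src + np.sqrt(1.0 - rho**2) * noise


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic two- or three-modality dataset."""
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_cells, spec.latent_dim, spec.n_clusters

    # cluster means scaled to the requested between/within variance ratio;
    # within-cluster latent noise has unit variance per dimension
    means = rng.standard_normal((k, d))
    means -= means.mean(axis=0)
    means *= np.sqrt(spec.separation) / max(means.std(), 1e-12)
    clusters = rng.integers(0, k, size=n)
    latent = means[clusters] + rng.standard_normal((n, d))

    def modality_signal(p: int) -> np.ndarray:
        w = rng.standard_normal((d, p)) / np.sqrt(d)
        return latent @ w  # noise added after linking

    y_signal = modality_signal(spec.p_y)
    z_signal = modality_signal(spec.p_z)
    # linked columns: y side keeps its standardized signal, z side tracks it at rho
    s = spec.s_linked
    y_signal[:, :s] = _standardize(y_signal[:, :s])
    z_signal[:, :s] = _linked_columns(y_signal[:, :s], spec.linkage_rho, rng)
    y = y_signal + spec.noise_sd_y * rng.standard_normal((n, spec.p_y))
    z = z_signal + spec.noise_sd_z * rng.standard_normal((n, spec.p_z))

    w_mat = None
    if spec.p_w is not None:
        if s > spec.p_w or s > spec.p_z:
            raise ParameterError("s_linked exceeds the third modality's feature count")
        w_signal = modality_signal(spec.p_w)
        w_signal[:, :s] = _linked_columns(z_signal[:, :s], spec.linkage_rho, rng)
        w_mat = w_signal + spec.noise_sd_w * rng.standard_normal((n, spec.p_w))

    if spec.dropout_rate_z > 0:
        z *= rng.random((n, spec.p_z)) >= spec.dropout_rate_z

    y_feats = [f"gene_{j:04d}" for j in range(spec.p_y)]
    z_feats = [f"prot_{j:04d}" for j in range(spec.p_z)]
    linkage_yz = LinkageMap(pairs=[(y_feats[j], z_feats[j]) for j in range(s)])
    linkage_zw = None
    w_feats = None
    if w_mat is not None:
        w_feats = [f"peak_{j:04d}" for j in range(spec.p_w)]
        linkage_zw = LinkageMap(pairs=[(z_feats[j], w_feats[j]) for j in range(s)])

    # optional removal of one cluster from one modality
    keep = {m: np.arange(n) for m in ("y", "z", "w")}
    if spec.missing_cluster_in is not None:
        mod, c = spec.missing_cluster_in
        keep[mod] = np.flatnonzero(clusters != c)

    def finish(mod: str, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Subset, shuffle; return (matrix, cluster labels, orig->row map)."""
        rows = keep[mod]
        perm = rng.permutation(len(rows)) if spec.shuffle else np.arange(len(rows))
        inv = np.full(n, -1, dtype=np.int64)
        inv[rows[perm]] = np.arange(len(rows))
        return mat[rows][perm], clusters[rows][perm], inv

    y_out, cl_y, inv_y = finish("y", y)
    z_out, cl_z, inv_z = finish("z", z)

    def pairing(inv_a: np.ndarray, inv_b: np.ndarray) -> np.ndarray:
        both = np.flatnonzero((inv_a >= 0) & (inv_b >= 0))
        return np.stack([inv_a[both], inv_b[both]], axis=1)

    w_ds = None
    pairing_zw = None
    cl_w = None
    if w_mat is not None:
        w_out, cl_w, inv_w = finish("w", w_mat)
        pairing_zw = pairing(inv_z, inv_w)
        w_ds = ModalityDataset(
            w_out, [f"wcell_{i}" for i in range(len(w_out))], w_feats,
            [f"cluster_{c}" for c in cl_w],
        )

    truth = SyntheticTruth(
        pairing_yz=pairing(inv_y, inv_z),
        pairing_zw=pairing_zw,
        clusters_y=np.array([f"cluster_{c}" for c in cl_y]),
        clusters_z=np.array([f"cluster_{c}" for c in cl_z]),
        clusters_w=None if cl_w is None else np.array([f"cluster_{c}" for c in cl_w]),
    )
    ds_y = ModalityDataset(
        y_out, [f"ycell_{i}" for i in range(len(y_out))], y_feats,
        truth.clusters_y.tolist(),
    )
    ds_z = ModalityDataset(
        z_out, [f"zcell_{i}" for i in range(len(z_out))], z_feats,
        truth.clusters_z.tolist(),
    )
    return SyntheticData(ds_y, ds_z, w_ds, linkage_yz, linkage_zw, truth, spec)


def reduce_panel(
    dataset: ModalityDataset,
    linkage: LinkageMap,
    keep_k: int,
    ranking: list[str] | None = None,
    side: str = "z",
) -> tuple[ModalityDataset, LinkageMap]:
    """Keep only the top-k linked features of the smaller panel.

    ``ranking`` lists this dataset's linked feature ids best-first; by
    default features are ranked by variance.  The dataset loses the dropped
    linked columns and the linkage is restricted accordingly.
    """
    linked_ids = [b if side == "z" else a for a, b in linkage.pairs]
    s = len(linked_ids)
    if not 1 <= keep_k <= s:
        raise ParameterError(f"keep_k={keep_k} must be in [1, s={s}]")
    if ranking is None:
        variances = {
            fid: dataset.matrix[:, dataset.feature_index(fid)].var()
            for fid in linked_ids
        }
        ranking = sorted(linked_ids, key=lambda f: -variances[f])
    kept = set(ranking[:keep_k])
    drop = set(linked_ids) - kept
    cols = [j for j, f in enumerate(dataset.feature_ids) if f not in drop]
    new_ds = ModalityDataset(
        dataset.matrix[:, cols],
        list(dataset.cell_ids),
        [dataset.feature_ids[j] for j in cols],
        dataset.cell_types,
    )
    new_pairs = [
        (a, b) for (a, b) in linkage.pairs if (b if side == "z" else a) in kept
    ]
    new_transforms = [
        t for (a, b), t in zip(linkage.pairs, linkage.transforms)
        if (b if side == "z" else a) in kept
    ]
    return new_ds, LinkageMap(pairs=new_pairs, transforms=new_transforms)
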