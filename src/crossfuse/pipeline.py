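"""End-to-end orchestration of the integration pipeline.

Stages, in order: normalization, meta-cell aggregation, all-feature k-NN
graphs, fuzzy smoothing of linked features, initial linear-assignment
matching, iterative refinement (CCA coembedding -> smoothing -> assignment),
pivot filtering, final CCA embedding, match propagation to unmatched
meta-cells, expansion to single cells, and Pearson scoring with optional
directional pruning.  A tri-modal mode chains two bimodal runs through the
shared middle modality and coembeds all three views with generalized CCA.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import OFF, PipelineConfig
from .datatypes import (
    LEVEL_METACELL,
    LEVEL_SINGLECELL,
    PROV_PROPAGATED,
    PROV_REFINED,
    LinkageMap,
    MatchTable,
    ModalityDataset,
)
from .embed import CCAModel, GCCAModel, PCAModel, cc_scores, cca_fit, gcca_fit, pca_fit
from .exceptions import ParameterError
from .graph import NeighborGraph, build_nn_graph, fuzzy_smooth, pairwise_distances
from .match import batched_match, cross_distance, initial_match, linear_assignment
from .preprocess import MetaCellMap, build_metacells, make_linked_matrices, normalize

logger = logging.getLogger(__name__)


@dataclass
class PipelineState:
    """Bookkeeping across refinement iterations."""

    iteration: int = 0
    match: MatchTable | None = None
    objectives: list[float] = field(default_factory=list)


@dataclass
class JointEmbedding:
    """Per-modality coordinates in the shared CCA space plus the model."""

    emb_y: np.ndarray
    emb_z: np.ndarray
    model: CCAModel


# ------------------------------------------------------------- refinement
def refine(
    initial: MatchTable,
    y_reduced: np.ndarray,
    z_reduced: np.ndarray,
    graph_y: NeighborGraph,
    graph_z: NeighborGraph,
    n_iter: int,
    w1: float,
    r_cc: int,
    ridge: float | None = None,
    metric: str = "correlation",
    batch_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> PipelineState:
    """Iterate CCA coembedding, fuzzy smoothing and linear assignment.

    Each iteration fits CCA on the current matched pairs of the PCA-reduced
    all-feature matrices, scores every meta-cell, smooths both score
    matrices with weight ``w1`` over the all-feature graphs, and re-solves
    the assignment on the smoothed coordinates.
    """
    state = PipelineState(iteration=0, match=initial, objectives=[initial.objective])
    current = initial
    for t in range(1, n_iter + 1):
        r_eff = min(r_cc, y_reduced.shape[1], z_reduced.shape[1], len(current) - 1)
        model = cca_fit(
            y_reduced[current.idx_a], z_reduced[current.idx_b], r_eff, ridge
        )
        sy = fuzzy_smooth(cc_scores(model, y_reduced, "y"), graph_y, w1)
        sz = fuzzy_smooth(cc_scores(model, z_reduced, "z"), graph_z, w1)
        if batch_size is not None and rng is not None:
            current = _batched_assignment(sy, sz, metric, batch_size, rng)
        else:
            current = linear_assignment(cross_distance(sy, sz, metric))
        state.iteration = t
        state.match = current
        state.objectives.append(current.objective)
        logger.info("refinement iteration %d: objective %.6g", t, current.objective)
    return state


def _batched_assignment(
    ys: np.ndarray, zs: np.ndarray, metric: str, batch_size: int,
    rng: np.random.Generator,
) -> MatchTable:
    """Assignment with the larger side partitioned into random batches."""
    n_y, n_z = ys.shape[0], zs.shape[0]
    if batch_size >= max(n_y, n_z):
        return linear_assignment(cross_distance(ys, zs, metric))
    larger_is_y = n_y >= n_z
    n_large = n_y if larger_is_y else n_z
    perm = rng.permutation(n_large)
    tables = []
    for chunk in np.array_split(perm, int(np.ceil(n_large / batch_size))):
        chunk = np.sort(chunk)
        if larger_is_y:
            sub = linear_assignment(cross_distance(ys[chunk], zs, metric))
            tables.append(MatchTable(chunk[sub.idx_a], sub.idx_b, sub.distance))
        else:
            sub = linear_assignment(cross_distance(ys, zs[chunk], metric))
            tables.append(MatchTable(sub.idx_a, chunk[sub.idx_b], sub.distance))
    return MatchTable.concat(tables)


# ---------------------------------------------------------------- pivots
def filter_pivots(table: MatchTable, alpha: float) -> MatchTable:
    """Retain the ceil((1-alpha)*n) smallest-distance pairs as refined pivots."""
    if not 0.0 <= alpha < 1.0:
        raise ParameterError(f"alpha={alpha} must be in [0, 1)")
    n_keep = int(np.ceil((1.0 - alpha) * len(table)))
    order = np.argsort(table.distance, kind="stable")[:n_keep]
    kept = table.subset(np.sort(order))
    return kept.with_provenance(PROV_REFINED)


def final_embedding(
    y_full: np.ndarray,
    z_full: np.ndarray,
    y_meta: np.ndarray,
    z_meta: np.ndarray,
    pivots: MatchTable,
    r_e: int,
    ridge: float | None = None,
) -> JointEmbedding:
    """CCA on the pivot meta-cell all-feature rows, applied to every single cell."""
    n_piv = len(pivots)
    r_eff = min(r_e, y_meta.shape[1], z_meta.shape[1], n_piv - 1)
    if r_eff < 1:
        raise ParameterError(f"r_e={r_e} infeasible with {n_piv} pivots")
    model = cca_fit(y_meta[pivots.idx_a], z_meta[pivots.idx_b], r_eff, ridge)
    return JointEmbedding(
        emb_y=cc_scores(model, y_full, "y"),
        emb_z=cc_scores(model, z_full, "z"),
        model=model,
    )


def propagate(
    pivots: MatchTable,
    y_meta_smoothed: np.ndarray,
    z_meta_smoothed: np.ndarray,
    percentile: float = 100.0,
    metric: str = "correlation",
) -> MatchTable:
    """Match leftover meta-cells through their nearest pivot member.

    For each unmatched meta-cell of one modality, find its nearest neighbor
    (within that modality, on the smoothed all-feature rows) among pivot
    members and inherit that pivot's cross-modal partner.  Pairs whose
    nearest-neighbor distance exceeds the given percentile of all such
    distances in that direction are dropped.  Both directions are run.
    """
    if len(pivots) == 0:
        raise ParameterError("cannot propagate from an empty pivot set")
    out: list[MatchTable] = []
    for side, (own, other) in enumerate(
        [(y_meta_smoothed, "z"), (z_meta_smoothed, "y")]
    ):
        members = pivots.idx_a if side == 0 else pivots.idx_b
        partners = pivots.idx_b if side == 0 else pivots.idx_a
        # first occurrence wins if a member somehow repeats
        uniq, first = np.unique(members, return_index=True)
        unmatched = np.setdiff1d(np.arange(own.shape[0]), uniq)
        if unmatched.size == 0:
            continue
        d = pairwise_distances(own[unmatched], own[uniq], metric)
        nn = np.argmin(d, axis=1)  # ties -> lower member index (np.unique sorts)
        nn_dist = d[np.arange(len(unmatched)), nn]
        thr = 0.0 if percentile == 0 else np.percentile(nn_dist, percentile)
        keep = nn_dist <= thr
        partner = partners[first][nn]
        if side == 0:
            idx_a, idx_b = unmatched[keep], partner[keep]
        else:
            idx_a, idx_b = partner[keep], unmatched[keep]
        out.append(
            MatchTable(idx_a, idx_b, nn_dist[keep],
                       provenance=PROV_PROPAGATED, level=LEVEL_METACELL)
        )
    return MatchTable.concat(out) if out else MatchTable(
        np.empty(0, int), np.empty(0, int), np.empty(0),
        provenance=PROV_PROPAGATED, level=LEVEL_METACELL,
    )


def expand_to_single_cells(
    meta_table: MatchTable, map_y: MetaCellMap, map_z: MetaCellMap
) -> MatchTable:
    """Every single-cell pair whose meta-cells are matched becomes a candidate."""
    idx_a, idx_b, dist, score, prov = [], [], [], [], []
    for row in range(len(meta_table)):
        ma = map_y.members(meta_table.idx_a[row])
        mb = map_z.members(meta_table.idx_b[row])
        idx_a.append(np.repeat(ma, len(mb)))
        idx_b.append(np.tile(mb, len(ma)))
        n = len(ma) * len(mb)
        dist.append(np.full(n, meta_table.distance[row]))
        score.append(np.full(n, meta_table.score[row]))
        prov.extend([meta_table.provenance[row]] * n)
    if not idx_a:
        return MatchTable(np.empty(0, int), np.empty(0, int), np.empty(0),
                          level=LEVEL_SINGLECELL)
    return MatchTable(
        np.concatenate(idx_a), np.concatenate(idx_b), np.concatenate(dist),
        np.concatenate(score), np.asarray(prov, dtype=object), LEVEL_SINGLECELL,
    )


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
    num = np.sum(ac * bc, axis=1)
    out = np.zeros(len(a))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def score_and_prune(
    table: MatchTable,
    emb_y: np.ndarray,
    emb_z: np.ndarray,
    direction: str = "none",
) -> MatchTable:
    """Attach Pearson matching scores; optionally keep one best pair per cell.

    ``direction='z_to_y'`` keeps, for each Z-cell, only its highest-scoring
    pair (ties broken towards the lower partner index); cells without any
    candidate pair remain unmatched.
    """
    if emb_y.shape[1] < 2 or emb_z.shape[1] < 2:
        raise ParameterError("matching scores need embeddings with >= 2 dimensions")
    if direction not in ("y_to_z", "z_to_y", "none"):
        raise ParameterError(f"unknown pruning direction {direction!r}")
    scored = table.subset(np.ones(len(table), dtype=bool))
    scored.score = _row_pearson(emb_y[table.idx_a], emb_z[table.idx_b])
    if direction == "none" or len(scored) == 0:
        return scored
    if direction == "z_to_y":
        group, partner = scored.idx_b, scored.idx_a
    else:
        group, partner = scored.idx_a, scored.idx_b
    order = np.lexsort((partner, -scored.score, group))
    g_sorted = group[order]
    keep_sorted = np.ones(len(order), dtype=bool)
    keep_sorted[1:] = g_sorted[1:] != g_sorted[:-1]
    mask = np.zeros(len(order), dtype=bool)
    mask[order[keep_sorted]] = True
    return scored.subset(mask)


def chain_pivots(pivots_ab: MatchTable, pivots_bc: MatchTable) -> np.ndarray:
    """Triples (a, b, c) with (a,b) a refined pivot and (b,c) a refined pivot.

    The middle modality's indices must refer to the same (meta-)cell index
    space in both tables; each b appears at most once in the output.
    """
    b_to_a: dict[int, int] = {}
    for a, b in zip(pivots_ab.idx_a.tolist(), pivots_ab.idx_b.tolist()):
        b_to_a.setdefault(b, a)
    triples = []
    seen: set[int] = set()
    for b, c in zip(pivots_bc.idx_a.tolist(), pivots_bc.idx_b.tolist()):
        if b in b_to_a and b not in seen:
            triples.append((b_to_a[b], b, c))
            seen.add(b)
    if not triples:
        warnings.warn("no chained pivots: the two pivot sets share no middle-modality cells",
                      stacklevel=2)
        return np.empty((0, 3), dtype=np.int64)
    return np.asarray(triples, dtype=np.int64)


# ----------------------------------------------------------- orchestration
@dataclass
class IntegrationResult:
    """Everything a bimodal run produces."""

    matching: MatchTable            # final single-cell matching (scored/pruned)
    pivots: MatchTable              # refined pivots, meta-cell level
    propagated: MatchTable          # propagated matches, meta-cell level
    embedding: JointEmbedding       # single-cell coordinates, r_e columns
    metacells_y: MetaCellMap
    metacells_z: MetaCellMap
    state: PipelineState
    config: PipelineConfig
    pca_y: PCAModel
    pca_z: PCAModel


def integrate(
    dataset_y: ModalityDataset,
    dataset_z: ModalityDataset,
    linkage: LinkageMap,
    config: PipelineConfig | None = None,
) -> IntegrationResult:
    """Run the full bimodal pipeline and return matching plus embeddings."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    ds_y = normalize(dataset_y, cfg.normalize1)
    ds_z = normalize(dataset_z, cfg.normalize2)
    y_linked, z_linked = make_linked_matrices(ds_y, ds_z, linkage)

    logger.info("building meta-cells")
    map_y = build_metacells(ds_y, y_linked, cfg.metacell_size1,
                            min(cfg.k_nn1, ds_y.n_cells - 1), cfg.seed,
                            cfg.r_y, cfg.distance_metric)
    map_z = build_metacells(ds_z, z_linked, cfg.metacell_size2,
                            min(cfg.k_nn2, ds_z.n_cells - 1), cfg.seed,
                            cfg.r_z, cfg.distance_metric)
    y_meta, z_meta = map_y.all_feature_means, map_z.all_feature_means
    n_y, n_z = map_y.n_meta, map_z.n_meta

    logger.info("building all-feature neighbor graphs (n_y=%d, n_z=%d)", n_y, n_z)
    pca_y = pca_fit(y_meta, min(cfg.r_y, y_meta.shape[1], n_y - 1))
    pca_z = pca_fit(z_meta, min(cfg.r_z, z_meta.shape[1], n_z - 1))
    graph_y = build_nn_graph(pca_y.scores, min(cfg.k_nn1, n_y), cfg.distance_metric)
    graph_z = build_nn_graph(pca_z.scores, min(cfg.k_nn2, n_z), cfg.distance_metric)

    logger.info("initial matching on smoothed linked features (s=%d)", linkage.s)
    ys0 = fuzzy_smooth(map_y.linked_feature_means, graph_y, cfg.w0)
    zs0 = fuzzy_smooth(map_z.linked_feature_means, graph_z, cfg.w0)
    if cfg.batch_size != OFF:
        initial = batched_match(ys0, zs0, cfg.batch_size, rng,
                                cfg.svd1, cfg.svd2, cfg.distance_metric)
    else:
        initial = initial_match(ys0, zs0, cfg.svd1, cfg.svd2, cfg.distance_metric)

    logger.info("refinement: %d iterations", cfg.n_iter)
    state = refine(
        initial, pca_y.scores, pca_z.scores, graph_y, graph_z,
        cfg.n_iter, cfg.w1, cfg.r_cc, metric=cfg.distance_metric,
        batch_size=None if cfg.batch_size == OFF else cfg.batch_size, rng=rng,
    )
    pivots = filter_pivots(state.match, cfg.alpha)
    logger.info("refined pivots: %d of %d pairs", len(pivots), len(state.match))

    embedding = final_embedding(
        ds_y.matrix, ds_z.matrix, y_meta, z_meta, pivots, cfg.r_e
    )
    y_meta_sm = fuzzy_smooth(y_meta, graph_y, cfg.w0)
    z_meta_sm = fuzzy_smooth(z_meta, graph_z, cfg.w0)
    propagated = propagate(pivots, y_meta_sm, z_meta_sm,
                           cfg.propagation_percentile, cfg.distance_metric)
    logger.info("propagation: %d additional meta-cell pairs", len(propagated))

    meta_full = MatchTable.concat([pivots, propagated])
    singles = expand_to_single_cells(meta_full, map_y, map_z)
    matching = score_and_prune(singles, embedding.emb_y, embedding.emb_z,
                               cfg.prune_direction)
    logger.info("final matching: %d single-cell pairs", len(matching))
    return IntegrationResult(
        matching=matching, pivots=pivots, propagated=propagated,
        embedding=embedding, metacells_y=map_y, metacells_z=map_z,
        state=state, config=cfg, pca_y=pca_y, pca_z=pca_z,
    )


@dataclass
class TrimodalResult:
    """Chained-pivot tri-modal integration output."""

    triples: np.ndarray                 # (n, 3) meta-cell pivot triples
    embeddings: list[np.ndarray]        # single-cell coordinates per modality
    model: GCCAModel
    result_12: IntegrationResult
    result_23: IntegrationResult


def integrate_trimodal(
    dataset_1: ModalityDataset,
    dataset_2: ModalityDataset,
    dataset_3: ModalityDataset,
    linkage_12: LinkageMap,
    linkage_23: LinkageMap,
    config: PipelineConfig | None = None,
) -> TrimodalResult:
    """Two chained bimodal runs with the middle modality as intermediary.

    Modality 2 must receive identical preprocessing in both runs so that
    its meta-cell index space is shared; its slot-2 parameters from the
    first run are therefore reused as slot-1 parameters in the second.
    """
    cfg = config or PipelineConfig()
    cfg_23 = dataclasses.replace(
        cfg,
        metacell_size1=cfg.metacell_size2, metacell_size2=cfg.metacell_size2,
        k_nn1=cfg.k_nn2, r_y=cfg.r_z, normalize1=cfg.normalize2,
    )
    res12 = integrate(dataset_1, dataset_2, linkage_12, cfg)
    res23 = integrate(dataset_2, dataset_3, linkage_23, cfg_23)
    # run-1 pivots are (mod1, mod2); run-2 pivots are (mod2, mod3); triples (1, 2, 3)
    triples = chain_pivots(res12.pivots, res23.pivots)
    views_meta = [
        res12.pca_y.scores,   # modality 1 reduced meta matrix
        res23.pca_y.scores,   # modality 2 reduced meta matrix (run-2 y side)
        res23.pca_z.scores,   # modality 3 reduced meta matrix
    ]
    if triples.shape[0] < 3:
        raise ParameterError(
            f"only {triples.shape[0]} chained pivots; cannot fit a tri-modal embedding"
        )
    r_eff = min(cfg.r_e, *[v.shape[1] for v in views_meta], triples.shape[0] - 1)
    model = gcca_fit([v[triples[:, i]] for i, v in enumerate(views_meta)], r_eff)
    singles = [
        normalize(dataset_1, cfg.normalize1).matrix,
        normalize(dataset_2, cfg.normalize2).matrix,
        normalize(dataset_3, cfg.normalize2).matrix,
    ]
    pcas = [res12.pca_y, res23.pca_y, res23.pca_z]
    embeddings = [
        model.transform(pcas[i].transform(singles[i]), view=i) for i in range(3)
    ]
    return TrimodalResult(
        triples=triples, embeddings=embeddings, model=model,
        result_12=res12, result_23=res23,
    )
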