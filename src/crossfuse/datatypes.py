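"""Core containers shared across the pipeline.

A :class:`ModalityDataset` is one modality's cells-by-features matrix with
row/column labels.  A :class:`LinkageMap` records which feature of one
modality is linked to (predictive of) which feature of the other, e.g. a
protein and its coding gene.  A :class:`MatchTable` is a list of cross-modal
index pairs with distances, optional matching scores and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

# provenance tags, in pipeline order
PROV_INITIAL = "initial"
PROV_REFINED = "refined_pivot"
PROV_PROPAGATED = "propagated"

LEVEL_METACELL = "metacell"
LEVEL_SINGLECELL = "singlecell"


@dataclass
class ModalityDataset:
    """Cells-by-features matrix for one modality.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_features)`` float array.
    cell_ids, feature_ids
        Row and column labels; feature ids must be unique.
    cell_types
        Optional per-cell annotation used only for evaluation.
    """

    matrix: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    cell_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise FormatError("matrix must be two-dimensional")
        n, p = self.matrix.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids were given"
            )
        if len(self.feature_ids) != p:
            raise FormatError(
                f"matrix has {p} columns but {len(self.feature_ids)} feature ids were given"
            )
        if len(set(self.feature_ids)) != p:
            raise FormatError("feature ids are not unique")
        if self.cell_types is not None and len(self.cell_types) != n:
            raise FormatError(
                f"matrix has {n} rows but {len(self.cell_types)} cell types were given"
            )
        bad = ~np.isfinite(self.matrix)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                "non-finite entry at cell "
                f"{self.cell_ids[i]!r} (row {i}), feature {self.feature_ids[j]!r} (column {j})"
            )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in dataset") from None


@dataclass
class LinkageMap:
    """One-to-one feature correspondence between two modalities.

    ``pairs[j] = (y_feature, z_feature)`` defines column ``j`` of both
    linked-feature matrices.  A pair may be tagged ``"precomputed-prediction"``
    when the referenced y-side column already holds a cross-modal prediction
    rather than a raw measurement; either way the named column is read as-is.
    """

    pairs: list[tuple[str, str]]
    transforms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise FormatError("no linked features")
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate feature pairs in linkage")
        if not self.transforms:
            self.transforms = ["identity"] * len(self.pairs)
        if len(self.transforms) != len(self.pairs):
            raise FormatError("transforms length does not match pairs")

    @property
    def s(self) -> int:
        """Number of linked feature pairs."""
        return len(self.pairs)


class MatchTable:
    """Cross-modal matched index pairs with distances and provenance.

    Indices are 0-based and may refer to meta-cells or single cells
    depending on ``level``.  Scores (Pearson correlation in the final joint
    embedding) are NaN until assigned by scoring.
    """

    def __init__(
        self,
        idx_a: np.ndarray,
        idx_b: np.ndarray,
        distance: np.ndarray,
        score: np.ndarray | None = None,
        provenance: np.ndarray | list[str] | str = PROV_INITIAL,
        level: np.ndarray | list[str] | str = LEVEL_METACELL,
    ) -> None:
        self.idx_a = np.asarray(idx_a, dtype=np.int64)
        self.idx_b = np.asarray(idx_b, dtype=np.int64)
        self.distance = np.asarray(distance, dtype=np.float64)
        n = len(self.idx_a)
        if len(self.idx_b) != n or len(self.distance) != n:
            raise FormatError("match table columns have unequal lengths")
        self.score = (
            np.full(n, np.nan) if score is None else np.asarray(score, dtype=np.float64)
        )
        if isinstance(provenance, str):
            provenance = [provenance] * n
        if isinstance(level, str):
            level = [level] * n
        self.provenance = np.asarray(provenance, dtype=object)
        self.level = np.asarray(level, dtype=object)
        if len(self.score) != n or len(self.provenance) != n or len(self.level) != n:
            raise FormatError("match table columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.idx_a)

    @property
    def objective(self) -> float:
        """Total assignment cost of the stored pairs."""
        return float(np.sum(self.distance))

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.idx_a.tolist(), self.idx_b.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "idx_mod1": self.idx_a,
                "idx_mod2": self.idx_b,
                "distance": self.distance,
                "score": self.score,
                "provenance": self.provenance,
                "level": self.level,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MatchTable":
        return cls(
            df["idx_mod1"].to_numpy(),
            df["idx_mod2"].to_numpy(),
            df["distance"].to_numpy(),
            df["score"].to_numpy(),
            df["provenance"].to_numpy(),
            df["level"].to_numpy(),
        )

    @classmethod
    def concat(cls, tables: list["MatchTable"]) -> "MatchTable":
        tables = [t for t in tables if len(t) > 0]
        if not tables:
            return cls(np.empty(0, int), np.empty(0, int), np.empty(0))
        return cls(
            np.concatenate([t.idx_a for t in tables]),
            np.concatenate([t.idx_b for t in tables]),
            np.concatenate([t.distance for t in tables]),
            np.concatenate([t.score for t in tables]),
            np.concatenate([t.provenance for t in tables]),
            np.concatenate([t.level for t in tables]),
        )

    def subset(self, mask: np.ndarray) -> "MatchTable":
        return MatchTable(
            self.idx_a[mask],
            self.idx_b[mask],
            self.distance[mask],
            self.score[mask],
            self.provenance[mask],
            self.level[mask],
        )

    def with_provenance(self, tag: str) -> "MatchTable":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.provenance = np.asarray([tag] * len(out), dtype=object)
        return out
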