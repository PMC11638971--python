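"""Readers and writers for matrices, link tables, match tables and embeddings.

Supported inputs: dense CSV/TSV (cells x features, header row of feature
ids) or MatrixMarket triplet plus feature/cell label files.  All indices in
output files are 0-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio

from .config import PipelineConfig
from .datatypes import LinkageMap, MatchTable, ModalityDataset
from .exceptions import DataError, FormatError

logger = logging.getLogger(__name__)


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_modality(
    path_matrix: str | Path,
    path_features: str | Path | None = None,
    path_cells: str | Path | None = None,
    path_celltypes: str | Path | None = None,
    transpose: bool = False,
) -> ModalityDataset:
    """Load one modality's cells-by-features matrix.

    Dense CSV/TSV input carries feature ids in its header row; label files
    override/supply them.  MatrixMarket input requires both label files.
    ``transpose`` flips a features-by-cells matrix into the expected
    orientation.
    """
    path_matrix = Path(path_matrix)
    if not path_matrix.exists():
        raise FormatError(f"matrix file {path_matrix} does not exist")
    is_mtx = path_matrix.suffix.lower() == ".mtx"
    if is_mtx:
        if path_features is None or path_cells is None:
            raise FormatError(
                f"MatrixMarket input {path_matrix} requires feature and cell label files"
            )
        matrix = np.asarray(spio.mmread(path_matrix).todense(), dtype=np.float64)
        features: list[str] | None = None
    else:
        df = pd.read_csv(path_matrix, sep=_sep_for(path_matrix))
        features = [str(c) for c in df.columns]
        matrix = df.to_numpy(dtype=np.float64)
    if transpose:
        matrix = matrix.T

    if path_features is not None:
        features = _read_lines(path_features)
    if features is None:  # pragma: no cover - guarded above
        raise FormatError("no feature ids available")
    if len(features) != matrix.shape[1]:
        raise FormatError(
            f"feature file {path_features} lists {len(features)} features "
            f"but matrix {path_matrix} has {matrix.shape[1]} columns"
        )
    if path_cells is not None:
        cells = _read_lines(path_cells)
        if len(cells) != matrix.shape[0]:
            raise FormatError(
                f"cell file {path_cells} lists {len(cells)} cells "
                f"but matrix {path_matrix} has {matrix.shape[0]} rows"
            )
    else:
        cells = [f"cell_{i}" for i in range(matrix.shape[0])]
    cell_types = None
    if path_celltypes is not None:
        cell_types = _read_lines(path_celltypes)
        if len(cell_types) != matrix.shape[0]:
            raise FormatError(
                f"cell-type file {path_celltypes} lists {len(cell_types)} entries "
                f"but matrix {path_matrix} has {matrix.shape[0]} rows"
            )
    try:
        return ModalityDataset(matrix, cells, features, cell_types)
    except DataError as err:
        raise DataError(f"{path_matrix}: {err}") from None


def read_linkage(
    path_table: str | Path,
    dataset_y: ModalityDataset,
    dataset_z: ModalityDataset,
) -> LinkageMap:
    """Read a two(or three)-column TSV of linked feature ids.

    Pairs referencing features absent from either modality are dropped with
    a log message; zero surviving pairs is fatal.
    """
    df = pd.read_csv(path_table, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"link table {path_table} needs at least two columns")
    fy = set(dataset_y.feature_ids)
    fz = set(dataset_z.feature_ids)
    pairs: list[tuple[str, str]] = []
    transforms: list[str] = []
    dropped = 0
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        tag = str(row[2]) if df.shape[1] > 2 and not pd.isna(row[2]) else "identity"
        if a in fy and b in fz:
            pairs.append((a, b))
            transforms.append(tag)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d link pairs with missing features", dropped)
    if not pairs:
        raise FormatError(f"no linked features survive from {path_table}")
    return LinkageMap(pairs=pairs, transforms=transforms)


# ----------------------------------------------------------------- writing
MATCH_HEADER = "# 0-based indices; idx_mod1/idx_mod2 refer to input row order\n"


def write_match_table(table: MatchTable, path: str | Path) -> None:
    if len(table) == 0:
        logger.warning("writing empty match table to %s", path)
    with open(path, "w") as fh:
        fh.write(MATCH_HEADER)
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_match_table(path: str | Path) -> MatchTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return MatchTable.from_frame(df)


def write_embedding(cell_ids: list[str], matrix: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(matrix, columns=[f"dim_{j}" for j in range(matrix.shape[1])])
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return df["cell_id"].astype(str).tolist(), df.iloc[:, 1:].to_numpy(dtype=np.float64)


def write_outputs(
    out_dir: str | Path,
    match_table: MatchTable,
    embeddings: dict[str, tuple[list[str], np.ndarray]],
    config: PipelineConfig | None = None,
    metrics: dict | None = None,
) -> dict[str, Path]:
    """Write the matching TSV, per-modality embedding CSVs, a config
    snapshot, and (optionally) a metrics JSON.  Returns written paths."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        p = out_dir / "matching.tsv"
        write_match_table(match_table, p)
        written["matching"] = p
        for name, (cell_ids, matrix) in embeddings.items():
            p = out_dir / f"embedding_{name}.csv"
            write_embedding(cell_ids, matrix, p)
            written[f"embedding_{name}"] = p
        if config is not None:
            p = out_dir / "run_config.yaml"
            config.to_yaml(p)
            written["config"] = p
        if metrics is not None:
            p = out_dir / "metrics.json"
            p.write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
            written["metrics"] = p
        return written
    except OSError as err:
        raise OSError(f"cannot write outputs to {out_dir}: {err}") from err
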