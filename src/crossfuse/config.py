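"""Pipeline configuration: every tunable knob with validation and YAML I/O.

Defaults follow the robust operating ranges reported for the method:
smoothing weights 0.7, three refinement iterations, 15-nearest-neighbor
graphs, 30 principal components per modality, a 20-dimensional joint
embedding, no pivot filtering (``alpha = 0``) and meta-cells of target size
2 on the richer (sequencing-like) modality only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .exceptions import ConfigError

# sentinel string used for "feature disabled" in size-like fields
OFF = "off"

_NORM_SCHEMES = ("none", "log1p_total_scaled", "zscore_per_feature", "log1p_then_zscore")
_PRUNE_DIRECTIONS = ("y_to_z", "z_to_y", "none")
_METRICS = ("correlation", "euclidean")


@dataclass
class PipelineConfig:
    """All tuning parameters of the integration pipeline."""

    #: smoothing weight for linked features at initialization, in [0, 1]
    w0: float = 0.7
    #: smoothing weight for embedding coordinates during refinement, in [0, 1]
    w1: float = 0.7
    #: number of refinement iterations (>= 1; 0 disables refinement)
    n_iter: int = 3
    #: neighborhood sizes of the all-feature k-NN graphs, per modality
    k_nn1: int = 15
    k_nn2: int = 15
    #: target mean meta-cell size per modality; "off" or 1 keeps single cells
    metacell_size1: Union[float, str] = 2
    metacell_size2: Union[float, str] = OFF
    #: SVD components for initial matching on smoothed linked features;
    #: None means min(30, number of linked features)
    svd1: int | None = None
    svd2: int | None = None
    #: PCA components for the all-feature matrices
    r_y: int = 30
    r_z: int = 30
    #: CCA embedding dimension during refinement
    r_cc: int = 20
    #: final joint-embedding dimension
    r_e: int = 20
    #: pivot filtering proportion in [0, 1); 0 keeps all pairs
    alpha: float = 0.0
    #: propagation distance threshold as a percentile in (0, 100]
    propagation_percentile: float = 100.0
    #: directional pruning of the single-cell matching
    prune_direction: str = "none"
    #: row-distance metric used throughout
    distance_metric: str = "correlation"
    #: RNG seed for Leiden clustering, batching and k-means
    seed: int = 0
    #: batch size for assignment on large inputs; "off" solves one problem
    batch_size: Union[int, str] = OFF
    #: per-modality normalization scheme applied on load
    normalize1: str = "none"
    normalize2: str = "none"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _range(name: str, value: float, lo: float, hi: float, *,
                   lo_open: bool = False, hi_open: bool = False) -> None:
            ok = (value > lo if lo_open else value >= lo) and (
                value < hi if hi_open else value <= hi
            )
            if not ok:
                raise ConfigError(f"config field {name}={value!r} out of range")

        _range("w0", self.w0, 0, 1)
        _range("w1", self.w1, 0, 1)
        if self.n_iter < 0:
            raise ConfigError(f"config field n_iter={self.n_iter} must be >= 0")
        for name in ("k_nn1", "k_nn2"):
            if getattr(self, name) < 2:
                raise ConfigError(f"config field {name}={getattr(self, name)} must be >= 2")
        for name in ("metacell_size1", "metacell_size2"):
            v = getattr(self, name)
            if v != OFF and (not isinstance(v, (int, float)) or v < 1):
                raise ConfigError(
                    f"config field {name}={v!r} must be a size >= 1 or {OFF!r}"
                )
        for name in ("svd1", "svd2"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ConfigError(f"config field {name}={v} must be >= 1 or null")
        for name in ("r_y", "r_z", "r_cc", "r_e"):
            if getattr(self, name) < 1:
                raise ConfigError(f"config field {name}={getattr(self, name)} must be >= 1")
        if self.r_cc > min(self.r_y, self.r_z):
            raise ConfigError(
                f"config field r_cc={self.r_cc} must be <= min(r_y, r_z)"
            )
        _range("alpha", self.alpha, 0, 1, hi_open=True)
        _range("propagation_percentile", self.propagation_percentile, 0, 100, lo_open=True)
        if self.prune_direction not in _PRUNE_DIRECTIONS:
            raise ConfigError(
                f"config field prune_direction={self.prune_direction!r} "
                f"must be one of {_PRUNE_DIRECTIONS}"
            )
        if self.distance_metric not in _METRICS:
            raise ConfigError(
                f"config field distance_metric={self.distance_metric!r} "
                f"must be one of {_METRICS}"
            )
        if self.batch_size != OFF and (
            not isinstance(self.batch_size, int) or self.batch_size < 2
        ):
            raise ConfigError(
                f"config field batch_size={self.batch_size!r} must be an int >= 2 or {OFF!r}"
            )
        for name in ("normalize1", "normalize2"):
            if getattr(self, name) not in _NORM_SCHEMES:
                raise ConfigError(
                    f"config field {name}={getattr(self, name)!r} "
                    f"must be one of {_NORM_SCHEMES}"
                )

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
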