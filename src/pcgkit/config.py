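"""Pipeline configuration, serializable to a human-readable YAML file."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._core import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with validated defaults."""

    sample_rate: float = 8000.0      # Hz; every recording is resampled to this
    normalize: bool = True           # z-score each recording before analysis
    mfcc_n_coeffs: int = 13
    mfcc_frame_len: float = 0.025    # seconds
    mfcc_hop: float = 0.010          # seconds
    mfcc_n_filters: int = 26
    mfcc_include_zeroth: bool = True
    n_bins: int = 10                 # quantile bins for chi-square ranking
    top_k: int = 15                  # features kept after selection
    knn_k: int = 10                  # weighted-KNN neighbour count
    train_fraction: float = 0.8      # stratified holdout split
    seed: int = 0                    # master seed for all randomness
    duration: float = 3.0            # seconds per simulated recording
    out_dir: str = "pcgkit_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if not 1 <= self.mfcc_n_coeffs <= self.mfcc_n_filters:
            raise ValidationError("mfcc_n_coeffs must be in [1, mfcc_n_filters]")
        if self.mfcc_frame_len <= 0 or self.mfcc_hop <= 0:
            raise ValidationError("MFCC frame length and hop must be positive")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if not 1 <= self.top_k <= 26:
            raise ValidationError("top_k must be in [1, 26]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be strictly between 0 and 1")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration (for reproducibility logs)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
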