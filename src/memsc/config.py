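"""Pipeline configuration: thresholds, tuning knobs, and provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .types import ValidationError, as_dict


@dataclass
class QCThresholds:
    """Per-condition cell filters; boundary values are kept (strict tests)."""

    min_features: int = 200
    max_features: int = 4000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_features <= 0 or self.max_features <= 0:
            raise ValidationError("feature thresholds must be positive")
        if self.min_features >= self.max_features:
            raise ValidationError("min_features must be < max_features")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in (0, 1]")


# Filters as stated for the two study arms: inflamed mucosa keeps cells
# with 200 < features < 4000 and mito <= 20%; normal mucosa keeps cells
# with 200 < features < 3000 and mito <= 40%.
QC_PRESETS = {
    "inflamed": QCThresholds(200, 4000, 0.20),
    "normal": QCThresholds(200, 3000, 0.40),
}


@dataclass
class PipelineConfig:
    """Every tunable of the analysis pipeline, with study defaults."""

    qc: dict = field(
        default_factory=lambda: {c: QC_PRESETS[c] for c in ("normal", "inflamed")}
    )
    scale_factor: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 30
    resolution: float = 0.6
    k_neighbors: int = 20
    n_bins: int = 25
    n_ctrl: int = 100
    lr_cutoff: float = 0.2
    n_perm: int = 1000
    mito_prefix: str = "Mt-"
    cd68_gene: str = "Cd68"
    min_marker_count: int = 1
    dual_quantile: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale_factor", "n_hvg", "n_pcs", "resolution",
                     "k_neighbors", "n_bins", "n_ctrl", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        qc = {}
        for cond, thr in self.qc.items():
            qc[cond] = thr if isinstance(thr, QCThresholds) else QCThresholds(**thr)
        self.qc = qc

    # -- provenance ------------------------------------------------------
    def to_dict(self) -> dict:
        return as_dict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def config_hash(obj) -> str:
    """Stable short hash of any dataclass / dict configuration."""
    blob = json.dumps(as_dict(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
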