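"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulted to the protocol values."""

    # filtering
    filter_low_hz: float = 1.0
    filter_high_hz: float = 40.0
    filter_window_s: float = 6.6
    # ICA EOG removal
    ica_components: int = 15
    ica_threshold: float = 0.8
    # epoching
    bandpower_epoch_s: float = 5.0
    bandpower_fs: float = 256.0
    connectivity_epoch_s: float = 2.5
    connectivity_fs: float = 128.0
    flat_ptp_uv: float = 1.0
    clean_folds: int = 10
    clean_max_interp: int = 3
    # epoch selection
    top_k_epochs: int = 50
    # connectivity
    mvar_order: int = 8
    mi_neighbors: int = 3
    # classification
    model_kind: str = "svm"
    reduction: str = "pca"
    cv_folds: int = 5
    split_ratio: float = 0.8
    n_surrogates: int = 100
    correlation_threshold: float = 0.92
    age_cut: float = 50.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
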