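"""Pipeline configuration: YAML-backed, schema-checked, fully seeded."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised with the list of offending configuration keys."""


@dataclass
class PipelineConfig:
    n_subjects: int = 10
    seed: int = 0
    activities: list[int] | None = None
    positions: list[int] | None = None
    epoch_length: int = 100
    wavelet: str = "db4"
    wavelet_level: int = 4
    denoise: bool = True
    lags: list[int] = field(default_factory=lambda: list(range(1, 11)))
    classifier: str = "elm"
    n_hidden: int = 300
    mrmr_depth: int = 60
    mi_bins: int = 10
    mi_row_cap: int = 12000
    ffs_row_cap: int = 30000
    ffs_patience: int = 5
    ffs_max_features: int = 30
    enter_count: int = 3
    hangover: int = 10
    out_dir: str = "sistdetect_out"

    def validate(self) -> None:
        errors = []
        if self.n_subjects < 1:
            errors.append("n_subjects: must be >= 1")
        if not self.lags or any(not 1 <= k <= 10 for k in self.lags):
            errors.append("lags: every lag count must lie in 1..10")
        if self.classifier not in ("elm", "mlp"):
            errors.append("classifier: must be 'elm' or 'mlp'")
        if self.epoch_length < 2:
            errors.append("epoch_length: must be >= 2")
        if self.mi_bins < 2:
            errors.append("mi_bins: must be >= 2")
        if self.enter_count < 1 or self.hangover < 1:
            errors.append("enter_count/hangover: must be >= 1")
        if self.activities is not None and \
                any(a not in range(1, 11) for a in self.activities):
            errors.append("activities: ids must lie in 1..10")
        if self.positions is not None and \
                any(p not in range(5) for p in self.positions):
            errors.append("positions: ids must lie in 0..4")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))

    def cascade_kwargs(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "mrmr_depth": self.mrmr_depth,
            "mi_bins": self.mi_bins,
            "mi_row_cap": self.mi_row_cap,
            "ffs_row_cap": self.ffs_row_cap,
            "ffs_patience": self.ffs_patience,
            "ffs_max_features": self.ffs_max_features,
            "enter_count": self.enter_count,
            "hangover": self.hangover,
        }

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")     # output location is not scientific config
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError("invalid configuration: unknown keys: "
                          + ", ".join(unknown))
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
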