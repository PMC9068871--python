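"""Run configuration: one YAML-serialisable object drives every command.

Defaults encode the canonical study conditions: 50/50 balanced train/test
division, 70/30 within-training resampling, ten divisions, a five-feature
signature.  Round counts default to desk scale (2,000 scoring / 200 ensemble
rounds); the full-scale settings are 1e5 and 1e4 rounds respectively —
identical estimator, just a longer average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InputError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    matrix_path: str = ""
    labels_path: str = ""
    output_dir: str = "permsig-out"
    orientation: str = "features-in-rows"
    delimiter: str = "\t"
    log2_transform: bool = False
    positive_label: str | None = None
    split_fraction: float = 0.5
    resample_fraction: float = 0.7
    n_rounds_scoring: int = 2000
    n_rounds_ensemble: int = 200
    divisions: int = 10
    k: int = 5
    root_seed: int = 0
    n_jobs: int = 1
    threshold_override: float | None = None
    pool_hyperparameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("split_fraction", "resample_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        for name in ("n_rounds_scoring", "n_rounds_ensemble", "divisions", "k"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def updated(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)
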