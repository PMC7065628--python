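"""Run configuration and seed derivation.

One master seed drives every stage through named substreams, so a full
pipeline run is reproducible end to end from a single YAML file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(seed: int, name: str) -> int:
    """Derive a deterministic per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    n_cells: int = 150
    skews: list[float] = field(
        default_factory=lambda: [0.13, 0.82, 0.26, 0.24, 0.74, 0.43])
    effect_scale: float = 1.0
    artifact_rates: dict = field(default_factory=dict)
    lifetime_min_ps: float = 200.0
    k_sigma: float = 2.0
    pad_side: int = 82
    model_kind: str = "lasso_cp"
    grid: list[dict] = field(default_factory=lambda: [{"lambda_": l} for l in
                                                      (0.001, 0.01, 0.1, 1.0)])
    holdout_donor: str | None = None
    feature_set: str = "cp123"
    backbone: str = "mini"

    def __post_init__(self) -> None:
        if not all(0.0 <= s <= 1.0 for s in self.skews):
            raise ValueError(
                f"skews must lie in [0, 1], got {self.skews}")
        for key, rate in self.artifact_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate {key}={rate} not in [0, 1]")
        if self.lifetime_min_ps <= 0:
            raise ValueError("lifetime_min_ps must be positive")
        if self.pad_side < 2:
            raise ValueError("pad_side too small")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
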