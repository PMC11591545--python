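"""Run-level configuration with provenance hashing.

A :class:`RunConfig` gathers the knobs shared across pipeline stages —
simulation sizes, protein-binding scenarios, PK/PD targets and the master
seed — and serializes itself (plus a short hash) into every output file
so results can be traced back to their settings.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .util import config_hash

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    dataset: str | None = None
    regimen: str = "1500-d1-d8-q6w"
    mic_distribution: str | None = None
    n_individuals: int = Field(10_000, ge=1)
    n_sim_vpc: int = Field(10_000, ge=1)
    n_boot: int = Field(1000, ge=1)
    n_cycles: int = Field(6, ge=1)
    pb_scenarios: list[float] = [93.0, 96.0, 97.0, 98.0, 99.0]
    targets: dict[str, float] = {"stasis": 27.1, "log1kill": 53.3, "log2kill": 111.1}
    seed: int = Field(1, ge=0)

    @field_validator("pb_scenarios")
    @classmethod
    def _pb_in_range(cls, v):
        for pb in v:
            if not (0 <= pb < 100):
                raise ValueError(f"protein-binding scenario {pb} outside [0, 100)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    @property
    def hash(self) -> str:
        return config_hash(self.model_dump())

    def meta(self, **extra) -> dict:
        out = {"config_hash": self.hash, "seed": self.seed}
        out.update(extra)
        return out
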