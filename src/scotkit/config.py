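"""Run configuration: schema, defaults, and TOML/JSON round-tripping.

Defaults reproduce the semi-infinite phantom of the linearity experiments
(mus' = 1/mm, mua = 0, Db0 = 1e-6 mm^2/s, 800 nm, Texp = 2 ms, beta = 1,
30 mm separation, alpha = 0.001).  Unknown keys are rejected so that typos
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .medium import BoxInclusion, OpticalMedium


class MediumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mua: float = 0.0
    musp: float = 1.0
    n: float = 1.33
    wavelength_nm: float = 800.0
    Db0: float = 1e-6

    def build(self) -> OpticalMedium:
        return OpticalMedium(**self.model_dump())


class InclusionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    rDb: float = 1.0

    def build(self) -> BoxInclusion:
        return BoxInclusion(tuple(self.center), tuple(self.size), self.rDb)


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lo: tuple[float, float, float] = (-30.0, -30.0, 0.0)
    hi: tuple[float, float, float] = (60.0, 30.0, 60.0)
    voxel_mm: float = 1.0


class TauGridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_log: int = 128
    tau_min: float = 1e-7


class RunConfig(BaseModel):
    """Fully serializable description of one forward/inverse run."""

    model_config = ConfigDict(extra="forbid")

    medium: MediumConfig = Field(default_factory=MediumConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    tau: TauGridConfig = Field(default_factory=TauGridConfig)
    probe: str = "hex"  # builtin name or optode CSV path
    inclusions: list[InclusionConfig] = Field(default_factory=list)
    method: str = "rytov"  # born | rytov | mc
    signal_kind: str = "inv_contrast"
    rho_mm: float = 30.0
    Texp: float = 2e-3
    beta: float = 1.0
    alpha: float = 1e-3
    n_photons: int = 1_000_000
    seed: int = 0
    out_dir: str = "scot_out"


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML or JSON config; empty files give defaults.

    Raises a validation error naming the offending key for unknown or
    ill-typed entries.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Archive a resolved config as JSON (load_config reads it back)."""
    Path(path).write_text(json.dumps(config.model_dump(), indent=2) + "\n")
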