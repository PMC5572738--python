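"""Run configuration: validated defaults for every pipeline stage.

A :class:`RunConfig` collects the geometry, assay and model defaults used
by the command-line tools, round-trips losslessly through JSON, and is
recorded in every run manifest so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .geometry import DEFAULT_AREA_PER_LIPID, DEFAULT_BILAYER_THICKNESS
from .occupancy import DEFAULT_RECONSTITUTABLE_FRACTION, FIT_RADIUS_PRESET
from .simulate import DEFAULT_K_RED


class GeometryConfig(BaseModel):
    area_per_lipid: float = Field(DEFAULT_AREA_PER_LIPID, gt=0)
    bilayer_thickness: float = Field(DEFAULT_BILAYER_THICKNESS, ge=0)


class AssayConfig(BaseModel):
    F0: float = Field(43.0, ge=0, le=100)
    Fmax: float = Field(76.2, ge=0, le=100)
    k_red: float = Field(DEFAULT_K_RED, gt=0)
    noise_sd: float = Field(0.5, ge=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.F0 <= self.Fmax:
            raise ValueError("F0 must not exceed Fmax")
        return self


class ModelConfig(BaseModel):
    r_bar: float = Field(FIT_RADIUS_PRESET["r_bar"], gt=0)
    sigma: float = Field(FIT_RADIUS_PRESET["sigma"], ge=0)
    f_reconstitutable: float = Field(DEFAULT_RECONSTITUTABLE_FRACTION, gt=0, le=1)


class RunConfig(BaseModel):
    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    assay: AssayConfig = Field(default_factory=AssayConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))
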