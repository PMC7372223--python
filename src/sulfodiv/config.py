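"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator


class RunConfig(BaseModel):
    """Everything a pipeline run needs, validated up front.

    Either ``input`` (a TIFF movie path) or ``preset`` (a strain preset
    name for simulation) must be given.  All detection thresholds are
    surfaced here with their documented defaults.
    """

    input: Optional[str] = None
    preset: Optional[str] = None
    n_cells: int = Field(default=60, ge=1)
    n_frames: int = Field(default=60, ge=2)
    frame_interval_s: float = Field(default=30.0, gt=0)
    pixel_size_um: float = Field(default=0.1235, gt=0)
    noise: bool = True
    drift_step_sd_px: float = Field(default=0.5, ge=0)

    membrane_channel: int = Field(default=0, ge=0)
    dna_channel: Optional[int] = 1

    min_area_px: int = Field(default=6, ge=1)
    smoothing_sigma_px: float = Field(default=1.0, gt=0)
    iou_link: float = Field(default=0.3, gt=0, lt=1)
    onset_frac: float = Field(default=0.8, gt=0, lt=1)
    recover_frac: float = Field(default=0.9, gt=0, le=1)
    persist_frames: int = Field(default=3, ge=1)
    solidity_min: float = Field(default=0.9, gt=0, le=1)
    area_frac_max: float = Field(default=0.25, gt=0, le=1)

    seed: int = 0
    outdir: str = "sulfodiv_out"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.input is None and self.preset is None:
            raise ValueError("either input or preset must be given")
        if not self.onset_frac < self.recover_frac:
            raise ValueError("onset_frac must be < recover_frac")
        return self

    @property
    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = self.model_dump_json().encode()
        return hashlib.sha256(blob).hexdigest()[:8]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
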