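"""Run configuration: schema-validated, loaded from TOML.

Unknown keys are rejected so that a typo in a config file fails loudly
before any computation starts.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ParameterError

__all__ = ["SegmentationSettings", "RunConfig", "load_config"]


class SegmentationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kernel_scale: float = Field(4.0, gt=0)
    length_weight: float = 0.002 * 255.0 ** 2
    regularization_weight: float = 1.0
    heaviside_width: float = Field(1.0, gt=0)
    time_step: float = Field(0.1, gt=0)
    max_iters: int = Field(500, ge=1)
    energy_tol: float = Field(1e-5, gt=0)
    bias_floor: float = Field(0.1, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input: str | None = None
    format: Literal["dicom", "nifti", "png"] | None = None
    slice_selector: int | None = None
    spacing: float | None = Field(None, gt=0)
    segmentation: SegmentationSettings = Field(default_factory=SegmentationSettings)
    override_mask: str | None = None
    roi_mode: Literal["file", "auto"] = "auto"
    roi_files: list[str] = Field(default_factory=list)
    n_rois: int = Field(4, ge=3)
    roi_arclength_mm: float | None = Field(None, gt=0)
    resample_step_px: float = Field(1.0, gt=0)
    order: Literal[2, 3, 4] = 4
    units: Literal["pixels", "mm"] = "pixels"
    statistic: Literal["rms", "mean_abs"] = "rms"
    min_rois: int = Field(3, ge=3)
    output_dir: str = "."
    seed: int = 0
    log_level: Literal["debug", "info", "warning", "error"] = "info"


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ParameterError(f"invalid config {path}:\n{exc}") from exc
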