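"""Run configuration: one validated schema for every tunable parameter.

None of the segmentation scales, iteration counts or windows below is
dictated by the measurement definitions themselves; they are the
pipeline's free parameters, centralised here so a run is fully described
by (inputs, config, seed).  Unknown keys are rejected rather than
silently ignored.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ColocConfig(_Strict):
    soma_sigma_um: float = Field(1.5, gt=0, description="blob-enhancement scale for somas")
    soma_min_volume_um3: float = Field(300.0, gt=0, description="volume floor for a soma component")
    ac_iterations: int = Field(10, ge=0)
    process_smooth_sigma_um: float = Field(0.0, ge=0)
    puncta_smooth_sigma_um: float = Field(0.15, ge=0)
    min_punctum_voxels: int = Field(2, ge=1)
    connectivity: int = Field(26)

    @model_validator(mode="after")
    def _check_conn(self):
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        return self


class IshConfig(_Strict):
    pixel_size_um: float = Field(0.5, gt=0)
    dog_sigma_small_px: float = Field(1.0, gt=0)
    dog_sigma_large_px: float = Field(4.0, gt=0)
    ac_iterations: int = Field(5, ge=0)
    background_disk_radius: int = Field(10, ge=1)
    cell_area_bounds_um2: tuple[float, float] = (20.0, 400.0)
    cr_prior: float = Field(0.8, gt=0, lt=1)
    statistical_unit: str = Field("image", pattern="^(image|cell)$")

    @model_validator(mode="after")
    def _check(self):
        if not self.dog_sigma_small_px < self.dog_sigma_large_px:
            raise ValueError("dog_sigma_small_px must be < dog_sigma_large_px")
        lo, hi = self.cell_area_bounds_um2
        if not 0 < lo < hi:
            raise ValueError("cell area bounds must be 0 < lo < hi")
        return self


class PprConfig(_Strict):
    baseline_window_s: float = Field(0.05, gt=0)
    peak_window_s: tuple[float, float] = (0.001, 0.015)
    blank_s: float = Field(0.001, ge=0)
    decay_fit_start_s: float = Field(0.006, gt=0)
    summation_correction: bool = True
    moderate_band: float = Field(0.1, ge=0)


class RunConfig(_Strict):
    """Top-level configuration for the CLI and batch runner."""

    seed: int = 0
    voxel_size_um: tuple[float, float, float] = (0.297, 0.1154, 0.1154)
    coloc: ColocConfig = ColocConfig()
    ish: IshConfig = IshConfig()
    ppr: PprConfig = PprConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
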