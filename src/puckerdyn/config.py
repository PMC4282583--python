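"""Run configuration: schema-validated YAML for spectrometer and fit settings."""

from __future__ import annotations

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .relaxation import SpectrometerContext

__all__ = ["SpectrometerBlock", "FitSettings", "RunConfig", "load_config"]


class SpectrometerBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nu_h_mhz: float = 600.13
    nu_c_mhz: float = 150.90
    r_ch_angstrom: float = 1.09
    n_h: int = 1
    delta_sigma_ppm: float = -43.0

    def to_context(self) -> SpectrometerContext:
        return SpectrometerContext(
            nu_h_mhz=self.nu_h_mhz, nu_c_mhz=self.nu_c_mhz,
            r_ch=self.r_ch_angstrom * 1e-10, n_h=self.n_h,
            delta_sigma_ppm=self.delta_sigma_ppm,
        )


class FitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    n_starts: int = 32
    xtol: float = 1e-12
    bounds_p_exo: tuple[float, float] = (-40.0, 70.0)
    bounds_p_endo: tuple[float, float] = (120.0, 260.0)
    bounds_chi_m: tuple[float, float] = (25.0, 55.0)
    bounds_x_endo: tuple[float, float] = (0.0, 1.0)

    def bounds(self):
        return (self.bounds_p_exo, self.bounds_p_endo,
                self.bounds_chi_m, self.bounds_x_endo)


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    spectrometer: SpectrometerBlock = Field(default_factory=SpectrometerBlock)
    fit: FitSettings = Field(default_factory=FitSettings)
    output_dir: str = "."


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
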