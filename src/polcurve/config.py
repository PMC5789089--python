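"""Validated run configuration: YAML round-trip with strict schema.

A single RunConfig bundles the optical, movie-generation and analysis
parameters of one run. Defaults are the microscope/simulation parameters
used throughout the package (penetration depth 100 nm, PSF FWHM 211 nm,
125 nm pixels, DiI tilt 70 deg, 2 nm grid). Unknown keys and out-of-range
values are rejected at load time, naming the offending key; every pipeline
run can echo its effective configuration next to its outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .optics import OpticalConfig
from .movie import MovieConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticsSection(_Strict):
    d: float = Field(100.0, gt=0, description="evanescent penetration depth (nm)")
    psf_fwhm: float = Field(211.0, gt=0, description="Gaussian PSF FWHM (nm)")
    pixel: float = Field(125.0, gt=0, description="camera pixel size (nm)")
    beta: float = Field(70.0, gt=0, lt=90, description="DiI dipole tilt (deg)")
    grid: float = Field(2.0, gt=0, description="fine simulation grid (nm)")
    photons: float = Field(1.0, gt=0)
    noise: bool = False

    @field_validator("pixel")
    @classmethod
    def _pixel_ge_grid(cls, v, info):
        grid = info.data.get("grid", 2.0)
        if v < grid:
            raise ValueError("pixel must be >= grid")
        return v

    def to_optical(self, seed: int = 0) -> OpticalConfig:
        return OpticalConfig(
            d=self.d,
            psf_fwhm=self.psf_fwhm,
            grid=self.grid,
            pixel=self.pixel,
            beta=self.beta,
            photons=self.photons,
            noise=self.noise,
            seed=seed,
        )


class MovieSection(_Strict):
    field_px: int = Field(128, ge=16)
    n_frames: int = Field(300, ge=2)
    frame_interval: float = Field(2.0, gt=0)
    n_events: int = Field(60, ge=0)
    camera_offset: float = Field(100.0, ge=0)
    s_plane_photons: float = Field(2000.0, gt=0)
    clathrin_background: float = Field(50.0, ge=0)
    dynamin_background: float = Field(50.0, ge=0)
    amplitude: float = Field(140.0, gt=0)
    noise: bool = True

    def to_movie(self, seed: int = 0) -> MovieConfig:
        return MovieConfig(
            field_px=self.field_px,
            n_frames=self.n_frames,
            frame_interval=self.frame_interval,
            camera_offset=self.camera_offset,
            s_plane_photons=self.s_plane_photons,
            clathrin_background=self.clathrin_background,
            dynamin_background=self.dynamin_background,
            noise=self.noise,
            seed=seed,
        )


class AnalysisSection(_Strict):
    baseline_window: int = Field(10, ge=3)
    k: float = Field(3.0, gt=0)
    m: int = Field(3, ge=1)
    coincidence_window: int = Field(2, ge=0)
    iso_radius: float = Field(5.0, gt=0)
    min_duration: int = Field(5, ge=1)
    r_sig: float = Field(3.0, gt=0)


class RunConfig(_Strict):
    """Top-level configuration: optics + movie + analysis + seed."""

    optics: OpticsSection = OpticsSection()
    movie: MovieSection = MovieSection()
    analysis: AnalysisSection = AnalysisSection()
    seed: int = 0
    version: str = "1"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (strict: unknown keys and
    out-of-range values raise with the offending key named)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
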