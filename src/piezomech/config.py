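"""Validated pipeline configuration (YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from piezomech import __version__


class OpticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    wavelength_nm: float = Field(546.0, gt=0)
    n_medium: float = Field(1.33, gt=0)
    i_min: float = 2000.0
    i_max: float = 10000.0
    noise_sd: float = Field(20.0, ge=0)
    calibrate_lo_pct: float = Field(0.5, ge=0, le=100)
    calibrate_hi_pct: float = Field(99.5, ge=0, le=100)

    @model_validator(mode="after")
    def _check(self):
        if self.i_max <= self.i_min:
            raise ValueError("i_max must exceed i_min")
        return self


class SpectralConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fs: float = Field(19.91, gt=0)
    n_frames: int = Field(2048, ge=8)
    pixel_nm: float = Field(180.0, gt=0)
    patch_um: float = Field(7.2, gt=0)
    n_q: int = Field(64, ge=2)
    fit_f_lo: float = Field(0.2, ge=0)
    fit_f_hi: float | None = None     # default 0.8 * fs / 2
    kappa_kbt: float = Field(15.0, gt=0)
    temperature_K: float = Field(300.0, gt=0)
    exposure: float | None = Field(1.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        import numpy as np

        q_min = 2 * np.pi / (self.patch_um * 1e-6)
        q_max = np.pi / (self.pixel_nm * 1e-9)
        if q_min >= q_max:
            raise ValueError("q_min >= q_max: patch must exceed pixel size")
        if self.fit_f_hi is not None and self.fit_f_hi <= self.fit_f_lo:
            raise ValueError("fit band is empty")
        return self

    def grid(self):
        from piezomech.model import SpectralGrid

        return SpectralGrid.from_pixel(pixel_nm=self.pixel_nm,
                                       patch_um=self.patch_um, n_q=self.n_q,
                                       fs=self.fs, n_frames=self.n_frames)

    def fit_band(self) -> tuple[float, float]:
        hi = self.fit_f_hi if self.fit_f_hi is not None else 0.8 * self.fs / 2
        return (self.fit_f_lo, hi)


class PolarityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    axis: str = "displacement"
    min_area: int = Field(50, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.axis not in ("displacement", "long-axis"):
            raise ValueError("axis must be 'displacement' or 'long-axis'")
        return self


class ColocConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_px: int = Field(15, ge=3)
    offset: float = 0.0
    size_min: int = Field(50, ge=1)
    size_max: int = Field(350, ge=1)
    n_sims: int = Field(100, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        return self


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    optics: OpticsConfig = OpticsConfig()
    spectral: SpectralConfig = SpectralConfig()
    polarity: PolarityConfig = PolarityConfig()
    coloc: ColocConfig = ColocConfig()
    seed: int = 0
    log_level: str = "INFO"


def validate_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; pydantic reports all schema
    violations at once.  An empty/missing file yields all defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


class RunManifest:
    """Reproducibility record: config hash, version, per-stage checksums."""

    def __init__(self, config: PipelineConfig):
        canonical = json.dumps(config.model_dump(), sort_keys=True)
        self.config_hash = hashlib.sha256(canonical.encode()).hexdigest()
        self.version = __version__
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, **outputs) -> None:
        entry = {"timestamp": time.time()}
        for name, path in outputs.items():
            p = Path(path)
            entry[name] = {
                "path": str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
        self.stages[stage] = entry

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages}, indent=2))
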