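"""Run configuration: validated, unit-annotated, YAML round-trippable.

Every numeric key carries its unit as a suffix (``line_period_us``,
``depth_um``, ``amplitudes_nm``); unknown keys — including a right name
with a wrong or missing unit suffix — are rejected with an error naming
the key.  The defaults are the packaged demo: the 850/55 nm source, the
100 us line camera, and the three-reflector middle-ear phantom.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import doppler as _dop
from . import simulate as _sim

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SourceConfig(_Strict):
    center_wavelength_nm: float = 850.0
    fwhm_bandwidth_nm: float = 55.0
    pixel_count: int = Field(default=1024, ge=16)

    def build(self) -> _sim.SourceSpectrum:
        return _sim.make_source(
            self.center_wavelength_nm, self.fwhm_bandwidth_nm, self.pixel_count
        )


class AcquisitionSection(_Strict):
    line_period_us: float = 100.0
    exposure_fraction: float = 0.9
    alines_per_frame: int = Field(default=256, ge=2)
    exposure_oversampling: int = Field(default=16, ge=1)
    noise_sd: float = Field(default=1e-3, ge=0)

    def build(self, seed: int = 0) -> _sim.AcquisitionConfig:
        return _sim.AcquisitionConfig(
            line_period_us=self.line_period_us,
            exposure_fraction=self.exposure_fraction,
            alines_per_frame=self.alines_per_frame,
            exposure_oversampling=self.exposure_oversampling,
            noise_sd=self.noise_sd,
            rng_seed=seed,
        )


class ReflectorConfig(_Strict):
    depth_um: float
    reflectivity: float = Field(gt=0, le=1)
    label: str = ""


def _default_reflectors() -> list[ReflectorConfig]:
    return [
        ReflectorConfig(depth_um=150.0, reflectivity=0.05, label="thick TM"),
        ReflectorConfig(depth_um=250.0, reflectivity=0.20, label="malleus"),
        ReflectorConfig(depth_um=350.0, reflectivity=0.02, label="thin TM"),
    ]


class PhantomConfig(_Strict):
    reflectors: list[ReflectorConfig] = Field(default_factory=_default_reflectors)
    medium_index: float = Field(default=1.0, ge=1.0)
    beam_angle_rad: float = Field(default=0.0, ge=0.0)

    def build(self) -> _sim.SamplePhantom:
        return _sim.SamplePhantom(
            reflectors=tuple(
                _sim.Reflector(r.depth_um, r.reflectivity, r.label)
                for r in self.reflectors
            ),
            medium_index=self.medium_index,
            beam_angle_rad=self.beam_angle_rad,
        )


class DopplerSection(_Strict):
    # N=2 (depth-only averaging) in the demo: lateral windows would smear
    # the kHz-rate phase waveform sampled at the 10 kHz line rate.
    window_depth: int = Field(default=4, ge=1)
    window_lateral: int = Field(default=2, ge=2)
    mask_threshold_db: float = -40.0
    window_name: Literal["none", "hann", "gaussian"] = "hann"

    def build(
        self, source: SourceConfig, acq: AcquisitionSection, phantom: PhantomConfig
    ) -> _dop.DopplerConfig:
        return _dop.DopplerConfig(
            window_depth=self.window_depth,
            window_lateral=self.window_lateral,
            line_rate_hz=1e6 / acq.line_period_us,
            center_wavelength_nm=source.center_wavelength_nm,
            medium_index=phantom.medium_index,
            beam_angle_rad=phantom.beam_angle_rad,
            mask_threshold_db=self.mask_threshold_db,
        )


def _default_amplitudes() -> dict[float, float]:
    # nm-scale displacement per stimulus frequency; the peak at 4 kHz
    # injects a resonance-like maximum for the packaged demo sweep.
    return {1000.0: 40.0, 2000.0: 60.0, 4000.0: 100.0, 6000.0: 70.0, 8000.0: 50.0}


class VibrometrySection(_Strict):
    frequencies_hz: list[float] = Field(
        default_factory=lambda: [0.0, 1000.0, 2000.0, 4000.0, 6000.0, 8000.0]
    )
    amplitudes_nm: dict[float, float] = Field(default_factory=_default_amplitudes)
    replicates: int = Field(default=10, ge=1)
    roi_half_depth_bins: int = Field(default=8, ge=1)
    signed_mean: bool = False


class RunConfig(_Strict):
    source: SourceConfig = Field(default_factory=SourceConfig)
    acquisition: AcquisitionSection = Field(default_factory=AcquisitionSection)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    doppler: DopplerSection = Field(default_factory=DopplerSection)
    vibrometry: VibrometrySection = Field(default_factory=VibrometrySection)
    output_dir: str = "doctvib_out"
    seed: int = 7
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    def user_set_keys(self) -> dict:
        """Provenance: which keys were user-supplied vs defaulted."""

        def walk(model: BaseModel) -> dict:
            out = {}
            for name in model.model_fields_set:
                value = getattr(model, name)
                out[name] = walk(value) if isinstance(value, BaseModel) else "user"
            return out

        return walk(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (``None`` -> defaults).

    Unknown keys (including wrongly unit-suffixed ones) raise a
    validation error naming the offending key.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 over the fully resolved configuration."""
    blob = yaml.safe_dump(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
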