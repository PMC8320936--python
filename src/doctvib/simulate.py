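"""Synthetic spectrometer-OCT interferograms of a vibrating layered phantom.

The forward model emulates a spectral-domain OCT system built around a
broadband source (Gaussian envelope, default 850 nm centre / 55 nm FWHM)
and a line-scan camera whose pixels sample the spectrum *uniformly in
wavelength* — hence nonuniformly in wavenumber k = 2pi/lambda, so the
reconstruction chain has to k-linearize before its FFT.

Each camera line integrates over a finite exposure window.  Sample motion
during that window washes the interference fringes out; the simulator
models this by averaging the instantaneous fringe pattern over a number of
sub-instants spanning the exposure, which is exact for arbitrary motion in
the limit of dense oversampling (a closed-form sinc factor for linear
drift then serves as an independent oracle in the tests, not as the
implementation).

Depths are one-way optical path lengths in air; the round-trip fringe
phase of a reflector at depth z seen at wavenumber k is 2*k*n*z with n the
medium refractive index, and axial motion projects onto the beam through
the cosine of the beam angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .spectral import SpectralFrame

__all__ = [
    "SourceSpectrum",
    "Reflector",
    "VibrationStimulus",
    "LinearDrift",
    "AcquisitionConfig",
    "SamplePhantom",
    "make_source",
    "reflector_position",
    "simulate_spectral_line",
    "simulate_bscan",
    "default_phantom",
]

#: half-span of the wavelength grid, in units of the source FWHM
GRID_HALFSPAN_FWHM = 1.6


@dataclass(frozen=True)
class SourceSpectrum:
    """Broadband source sampled on the camera's wavelength grid.

    ``wavelength_nm`` is strictly increasing and spans
    centre +/- 1.6 x FWHM; ``envelope`` is the (nonnegative) Gaussian
    spectral power at each pixel, normalised to peak 1.
    """

    center_wavelength_nm: float
    fwhm_bandwidth_nm: float
    wavelength_nm: np.ndarray
    envelope: np.ndarray

    @property
    def pixel_count(self) -> int:
        return self.wavelength_nm.size


@dataclass(frozen=True)
class Reflector:
    """A discrete sample interface at a fixed resting depth."""

    depth_um: float
    reflectivity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.depth_um <= 0:
            raise ValueError(f"reflector depth must be positive, got {self.depth_um}")
        if not 0 < self.reflectivity <= 1:
            raise ValueError(
                f"reflectivity must lie in (0, 1], got {self.reflectivity}"
            )


@dataclass(frozen=True)
class VibrationStimulus:
    """Sinusoidal axial motion driven by a pure-tone acoustic stimulus.

    ``frequency_hz == 0`` means the control condition (no sound); the
    amplitude is then ignored.  ``target_labels`` restricts the motion to
    the named reflectors; ``None`` moves every reflector.
    """

    frequency_hz: float
    displacement_amplitude_nm: float = 0.0
    phase_offset_rad: float = 0.0
    target_labels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.frequency_hz < 0:
            raise ValueError("stimulus frequency must be >= 0")
        if self.displacement_amplitude_nm < 0:
            raise ValueError("displacement amplitude must be >= 0")

    def displacement_nm(self, t_s) -> np.ndarray:
        """Axial displacement (nm) at time ``t_s`` (s, scalar or array)."""
        t = np.asarray(t_s, dtype=float)
        if self.frequency_hz == 0.0 or self.displacement_amplitude_nm == 0.0:
            return np.zeros_like(t)
        return self.displacement_amplitude_nm * np.sin(
            2.0 * np.pi * self.frequency_hz * t + self.phase_offset_rad
        )

    def applies_to(self, label: str) -> bool:
        return self.target_labels is None or label in self.target_labels


@dataclass(frozen=True)
class LinearDrift:
    """Constant-velocity axial motion (fringe-washout characterisation)."""

    velocity_nm_per_s: float
    target_labels: frozenset[str] | None = None

    def displacement_nm(self, t_s) -> np.ndarray:
        return self.velocity_nm_per_s * np.asarray(t_s, dtype=float)

    def applies_to(self, label: str) -> bool:
        return self.target_labels is None or label in self.target_labels


@dataclass(frozen=True)
class AcquisitionConfig:
    """Line-camera timing and noise parameters.

    The camera line period defaults to 100 us (10 kHz A-line rate, i.e. a
    5 kHz Doppler Nyquist limit); the exposure covers
    ``exposure_fraction`` of each period and is resolved into
    ``exposure_oversampling`` sub-instants for the washout average.
    ``noise_sd`` is additive Gaussian noise relative to the envelope peak.
    """

    line_period_us: float = 100.0
    exposure_fraction: float = 0.9
    alines_per_frame: int = 256
    exposure_oversampling: int = 16
    noise_sd: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.line_period_us <= 0:
            raise ValueError("line_period_us must be positive")
        if not 0 < self.exposure_fraction <= 1:
            raise ValueError("exposure_fraction must lie in (0, 1]")
        if self.exposure_oversampling < 1:
            raise ValueError("exposure_oversampling must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def line_period_s(self) -> float:
        return self.line_period_us * 1e-6

    @property
    def exposure_s(self) -> float:
        return self.exposure_fraction * self.line_period_s

    @property
    def line_rate_hz(self) -> float:
        return 1.0 / self.line_period_s


@dataclass(frozen=True)
class SamplePhantom:
    """Ground-truth reflector stack with medium index and beam geometry."""

    reflectors: tuple[Reflector, ...]
    medium_index: float = 1.0
    beam_angle_rad: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reflectors", tuple(self.reflectors))
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if not 0 <= self.beam_angle_rad < np.pi / 2:
            raise ValueError("beam_angle_rad must lie in [0, pi/2)")


def default_phantom() -> SamplePhantom:
    """Three-reflector middle-ear stand-in: thick TM, malleus, thin TM."""
    return SamplePhantom(
        reflectors=(
            Reflector(depth_um=150.0, reflectivity=0.05, label="thick TM"),
            Reflector(depth_um=250.0, reflectivity=0.20, label="malleus"),
            Reflector(depth_um=350.0, reflectivity=0.02, label="thin TM"),
        ),
        medium_index=1.0,
        beam_angle_rad=0.0,
    )


def make_source(
    center_nm: float = 850.0, fwhm_nm: float = 55.0, pixel_count: int = 1024
) -> SourceSpectrum:
    """Gaussian source envelope on a wavelength-uniform camera grid.

    The grid spans centre +/- 1.6 x FWHM uniformly in wavelength, which is
    deliberately nonuniform in wavenumber so the k-linearization step of
    the reconstruction chain is exercised.
    """
    if center_nm <= 0 or fwhm_nm <= 0:
        raise ValueError("center and FWHM must be positive")
    if pixel_count < 16:
        raise ValueError("pixel_count must be >= 16")
    half = GRID_HALFSPAN_FWHM * fwhm_nm
    lam = np.linspace(center_nm - half, center_nm + half, pixel_count)
    envelope = np.exp(-4.0 * np.log(2.0) * ((lam - center_nm) / fwhm_nm) ** 2)
    return SourceSpectrum(
        center_wavelength_nm=center_nm,
        fwhm_bandwidth_nm=fwhm_nm,
        wavelength_nm=lam,
        envelope=envelope,
    )


def reflector_position(
    stimulus: VibrationStimulus | LinearDrift, base_depth_um: float, t_s
) -> np.ndarray:
    """Reflector depth (um, optical path in air) at time ``t_s``.

    z(t) = base + a*sin(2*pi*f*t + phi0) for a sinusoidal stimulus; the
    control stimulus (f = 0) returns the base depth at all times.  Beam
    projection is *not* applied here — it belongs to the interferometric
    forward model.
    """
    return base_depth_um + stimulus.displacement_nm(t_s) * 1e-3


def _total_displacement_nm(
    stimuli: Sequence[VibrationStimulus | LinearDrift], label: str, t_s: np.ndarray
) -> np.ndarray:
    disp = np.zeros_like(np.asarray(t_s, dtype=float))
    for stim in stimuli:
        if stim.applies_to(label):
            disp = disp + stim.displacement_nm(t_s)
    return disp


def simulate_spectral_line(
    phantom: SamplePhantom,
    stimuli: Sequence[VibrationStimulus | LinearDrift],
    source: SourceSpectrum,
    t_s: float,
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One camera line starting at time ``t_s`` (s).

    Per pixel of wavelength lambda the noiseless intensity is

        S(lambda) * [1 + sum_r 2*sqrt(R_r)*cos(4*pi*n*z_r(t')/lambda)]

    averaged over ``exposure_oversampling`` sub-instants t' spanning the
    exposure window (the fringe-washout model), with the motion projected
    onto the beam by cos(beam angle).  Additive Gaussian noise of standard
    deviation ``noise_sd`` x envelope peak is drawn from ``rng`` if the
    configured noise is nonzero.  An empty reflector list yields the bare
    source envelope.
    """
    if rng is None:
        rng = np.random.default_rng(acq.rng_seed)
    k = 2.0 * np.pi / source.wavelength_nm  # rad/nm, decreasing across pixels
    n_sub = acq.exposure_oversampling
    # midpoint sub-instants across the exposure window
    sub_t = t_s + (np.arange(n_sub) + 0.5) * (acq.exposure_s / n_sub)
    proj = np.cos(phantom.beam_angle_rad)

    fringe = np.zeros((source.pixel_count, n_sub))
    for refl in phantom.reflectors:
        disp_nm = _total_displacement_nm(stimuli, refl.label, sub_t)  # (n_sub,)
        z_nm = refl.depth_um * 1e3 + proj * disp_nm
        phase = 2.0 * phantom.medium_index * np.outer(k, z_nm)  # (pix, n_sub)
        fringe += 2.0 * np.sqrt(refl.reflectivity) * np.cos(phase)

    line = source.envelope * (1.0 + fringe.mean(axis=1))
    if acq.noise_sd > 0:
        line = line + rng.normal(
            0.0, acq.noise_sd * source.envelope.max(), size=line.shape
        )
    return line


def simulate_bscan(
    phantom: SamplePhantom,
    stimuli: Sequence[VibrationStimulus | LinearDrift],
    source: SourceSpectrum,
    acq: AcquisitionConfig,
    seed: int | None = None,
) -> SpectralFrame:
    """Simulate a full B-scan of ``alines_per_frame`` consecutive lines.

    A-line j starts at t = j x line period; recorded timestamps are these
    start times.  With a fixed seed and configuration the output is
    bit-identical across calls.
    """
    if acq.alines_per_frame < 2:
        raise ValueError("alines_per_frame must be >= 2 (Doppler needs A-line pairs)")
    rng = np.random.default_rng(acq.rng_seed if seed is None else seed)
    n_alines = acq.alines_per_frame
    spectra = np.empty((source.pixel_count, n_alines))
    for j in range(n_alines):
        spectra[:, j] = simulate_spectral_line(
            phantom, stimuli, source, j * acq.line_period_s, acq, rng=rng
        )
    timestamps = np.arange(n_alines) * acq.line_period_us
    return SpectralFrame(
        spectra=spectra,
        wavelength_nm=source.wavelength_nm.copy(),
        timestamp_us=timestamps,
        line_period_us=acq.line_period_us,
        k_uniform=False,
    )
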