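"""Kasai autocorrelation Doppler phase estimation and velocity conversion.

The phase difference between adjacent A-lines at a depth pixel is
estimated as the argument of the lag-one complex autocorrelation,
spatially averaged over an M (depth) x N (A-line) window:

    dphi = atan2( sum Im(conj(z_{m,n}) z_{m,n+1}),
                  sum Re(conj(z_{m,n}) z_{m,n+1}) )  in (-pi, pi]

with the sums running over the window's M depth rows and its N-1 adjacent
A-line pairs.  The Doppler frequency is fD = dphi * line_rate / (2*pi) and
the axial velocity v = lambda0 * fD / (2 * n_t * cos(theta)), with n_t the
tissue refractive index and theta the angle between the beam and the
motion axis.

Sign convention: motion that increases the optical path (away from the
sample arm) gives positive phase, so dphi ~ (4*pi*n_t*cos(theta)/lambda0)
x (displacement between consecutive lines).  No phase unwrapping is
performed; phase excursions beyond +/-pi alias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import ComplexBScan, StructuralImage

__all__ = [
    "DopplerConfig",
    "DopplerPhaseMap",
    "VelocityMap",
    "kasai_phase",
    "phase_to_frequency",
    "doppler_velocity",
    "velocity_map",
    "nyquist_limit",
    "alias_frequency",
    "intensity_mask",
    "pair_mask",
    "phase_trace",
    "dominant_frequency",
]


@dataclass(frozen=True)
class DopplerConfig:
    """Kasai window, acquisition rate, and velocity-conversion parameters.

    ``window_depth`` (M) counts depth rows, ``window_lateral`` (N) counts
    A-lines, i.e. N-1 adjacent A-line pairs enter each window.
    ``mask_threshold_db`` is the structural-intensity gate, expressed
    relative to the image peak (negative dB).
    """

    window_depth: int = 4
    window_lateral: int = 4
    line_rate_hz: float = 10_000.0
    center_wavelength_nm: float = 850.0
    medium_index: float = 1.0
    beam_angle_rad: float = 0.0
    mask_threshold_db: float = -40.0
    edge_policy: str = "shrink"

    def __post_init__(self) -> None:
        if self.window_depth < 1:
            raise ValueError("window_depth (M) must be >= 1")
        if self.window_lateral < 2:
            raise ValueError("window_lateral (N) must be >= 2")
        if self.line_rate_hz <= 0:
            raise ValueError("line_rate_hz must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if not 0 <= self.beam_angle_rad < np.pi / 2:
            raise ValueError("beam_angle_rad must lie in [0, pi/2)")
        if self.edge_policy not in ("shrink", "strict"):
            raise ValueError("edge_policy must be 'shrink' or 'strict'")


@dataclass
class DopplerPhaseMap:
    """Per-pixel phase difference, depth bin x A-line pair, in (-pi, pi]."""

    phase: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.phase.shape != self.valid_mask.shape:
            raise ValueError("phase and valid_mask shapes must match")


@dataclass
class VelocityMap:
    """Signed axial velocity (um/s) and Doppler frequency (Hz) maps."""

    velocity_um_s: np.ndarray
    frequency_hz: np.ndarray


def _box_sum(a: np.ndarray, m: int, k: int) -> np.ndarray:
    """Sum of ``a`` over an m x k window centred on each element.

    Windows shrink at the borders (sum over the in-bounds part only).
    Centering: rows span [i - (m-1)//2, i - (m-1)//2 + m), likewise for
    columns — the same convention the literal double-sum oracle uses.
    """
    h, w = a.shape
    cs = np.zeros((h + 1, w + 1))
    cs[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    i = np.arange(h)
    r0 = np.clip(i - (m - 1) // 2, 0, h)
    r1 = np.clip(i - (m - 1) // 2 + m, 0, h)
    j = np.arange(w)
    c0 = np.clip(j - (k - 1) // 2, 0, w)
    c1 = np.clip(j - (k - 1) // 2 + k, 0, w)
    return (
        cs[np.ix_(r1, c1)] - cs[np.ix_(r0, c1)] - cs[np.ix_(r1, c0)] + cs[np.ix_(r0, c0)]
    )


def kasai_phase(bscan: ComplexBScan, cfg: DopplerConfig) -> DopplerPhaseMap:
    """Windowed lag-one autocorrelation phase between adjacent A-lines.

    Output shape: depth bins x (A-lines - 1) pairs.  The window shrinks at
    the image borders under the default edge policy; ``"strict"`` raises
    if the window exceeds the image instead.
    """
    field = bscan.field
    if field.shape[1] < 2:
        raise ValueError("Doppler estimation needs at least 2 A-lines")
    m, n = cfg.window_depth, cfg.window_lateral
    n_pairs = field.shape[1] - 1
    if cfg.edge_policy == "strict" and (m > field.shape[0] or (n - 1) > n_pairs):
        raise ValueError("averaging window exceeds the image (strict edge policy)")
    corr = np.conj(field[:, :-1]) * field[:, 1:]
    num = _box_sum(corr.imag, m, n - 1)
    den = _box_sum(corr.real, m, n - 1)
    phase = np.arctan2(num, den)
    # deterministic boundary: map the -pi branch onto +pi
    phase[phase <= -np.pi] = np.pi
    return DopplerPhaseMap(phase=phase, valid_mask=np.ones_like(phase, dtype=bool))


def phase_to_frequency(pmap: DopplerPhaseMap, cfg: DopplerConfig) -> np.ndarray:
    """Doppler frequency fD = dphi * line_rate / (2*pi), in Hz.

    The representable range is +/- line_rate/2 (the phase Nyquist band).
    """
    return pmap.phase * cfg.line_rate_hz / (2.0 * np.pi)


def doppler_velocity(frequency_hz, cfg: DopplerConfig):
    """Axial velocity v = lambda0*fD / (2*n_t*cos(theta)), in um/s."""
    cos_theta = np.cos(cfg.beam_angle_rad)
    if cos_theta <= 0:
        raise ValueError("beam angle must have a positive cosine")
    lam_um = cfg.center_wavelength_nm * 1e-3
    return lam_um * np.asarray(frequency_hz) / (2.0 * cfg.medium_index * cos_theta)


def velocity_map(pmap: DopplerPhaseMap, cfg: DopplerConfig) -> VelocityMap:
    freq = phase_to_frequency(pmap, cfg)
    return VelocityMap(velocity_um_s=doppler_velocity(freq, cfg), frequency_hz=freq)


def nyquist_limit(line_period_s: float) -> float:
    """Highest unaliased Doppler frequency, 1/(2 x line period), in Hz."""
    if line_period_s <= 0:
        raise ValueError("line period must be positive")
    return 1.0 / (2.0 * line_period_s)


def alias_frequency(true_freq_hz: float, line_rate_hz: float) -> float:
    """Apparent frequency of ``true_freq_hz`` sampled at ``line_rate_hz``.

    Standard folding: |f - round(f/fs)*fs|, always <= fs/2.
    """
    if true_freq_hz <= 0 or line_rate_hz <= 0:
        raise ValueError("frequencies must be positive")
    return abs(true_freq_hz - round(true_freq_hz / line_rate_hz) * line_rate_hz)


def intensity_mask(structural: StructuralImage, threshold_db: float) -> np.ndarray:
    """True where the structural image is at least ``threshold_db``.

    The threshold is absolute (same dB scale as the image) and must lie
    within the image's [floor, ceiling] display range.
    """
    if not structural.floor_db <= threshold_db <= structural.ceiling_db:
        raise ValueError(
            f"threshold {threshold_db} dB outside display range "
            f"[{structural.floor_db}, {structural.ceiling_db}] dB"
        )
    return structural.log_magnitude_db >= threshold_db


def pair_mask(mask: np.ndarray) -> np.ndarray:
    """A-line-pair validity: both members of each adjacent pair pass."""
    return mask[:, :-1] & mask[:, 1:]


def phase_trace(
    bscan: ComplexBScan, cfg: DopplerConfig, depth_bin: int | None = None
) -> np.ndarray:
    """Per-pair phase-difference time series at one depth bin.

    Uses an M x 1-pair window (depth averaging only) so the temporal
    waveform is not smeared across A-line pairs.  ``depth_bin=None``
    selects the brightest depth (mean |field| across A-lines).
    """
    if depth_bin is None:
        depth_bin = int(np.abs(bscan.field).mean(axis=1).argmax())
    trace_cfg = DopplerConfig(
        window_depth=cfg.window_depth,
        window_lateral=2,
        line_rate_hz=cfg.line_rate_hz,
        center_wavelength_nm=cfg.center_wavelength_nm,
        medium_index=cfg.medium_index,
        beam_angle_rad=cfg.beam_angle_rad,
        mask_threshold_db=cfg.mask_threshold_db,
        edge_policy=cfg.edge_policy,
    )
    return kasai_phase(bscan, trace_cfg).phase[depth_bin, :]


def dominant_frequency(
    trace: np.ndarray, line_rate_hz: float, pad_factor: int = 16
) -> float:
    """Dominant oscillation frequency of a phase trace, in Hz.

    Zero-padded FFT peak with parabolic interpolation on the log
    magnitude; the mean is removed first so DC never wins.
    """
    x = np.asarray(trace, dtype=float) - np.mean(trace)
    n = pad_factor * x.size
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=n))
    peak = int(spec.argmax())
    if 0 < peak < spec.size - 1:
        la, lb, lc = np.log(spec[peak - 1 : peak + 2] + 1e-300)
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return (peak + delta) * line_rate_hz / n
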