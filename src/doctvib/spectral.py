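"""Spectral-domain OCT reconstruction: raw camera spectra to complex A-scans.

The processing chain is the batch equivalent of a real-time SD-OCT engine:
background subtraction, k-linearization (resampling the wavelength-uniform
camera grid onto a wavenumber-uniform grid), apodization, FFT to depth, and
log scaling for structural display.  The complex field is preserved end to
end because the Doppler stage needs its in-phase (I) and quadrature (Q)
components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "SpectralFrame",
    "ComplexBScan",
    "StructuralImage",
    "subtract_background",
    "k_linearize",
    "apodize",
    "to_ascans",
    "log_magnitude",
    "depth_axis_for",
]

#: zero-padding factor applied before the depth FFT (halves bin quantization)
DEFAULT_PAD_FACTOR = 2
#: relative offset added inside the log to avoid -inf on empty pixels
LOG_EPS_REL = 1e-12


@dataclass
class SpectralFrame:
    """Raw (or partially processed) camera spectra for one B-scan.

    ``spectra`` is pixel x A-line; ``wavelength_nm`` is strictly
    increasing with one entry per pixel; ``timestamp_us`` holds the A-line
    start times, uniformly spaced by ``line_period_us``.  ``k_uniform``
    records whether the frame has been resampled onto a
    wavenumber-uniform grid (a precondition of the FFT stage).
    """

    spectra: np.ndarray
    wavelength_nm: np.ndarray
    timestamp_us: np.ndarray
    line_period_us: float
    k_uniform: bool = False

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.timestamp_us = np.asarray(self.timestamp_us, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (pixel x A-line)")
        if self.wavelength_nm.size != self.spectra.shape[0]:
            raise ValueError("wavelength grid length must equal the pixel dimension")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.timestamp_us.size != self.spectra.shape[1]:
            raise ValueError("one timestamp per A-line required")
        if self.timestamp_us.size >= 2:
            dt = np.diff(self.timestamp_us)
            if np.any(dt <= 0) or not np.allclose(dt, self.line_period_us, rtol=1e-9):
                raise ValueError("timestamps must increase by exactly line_period_us")

    @property
    def n_alines(self) -> int:
        return self.spectra.shape[1]

    @property
    def pixel_count(self) -> int:
        return self.spectra.shape[0]


@dataclass
class ComplexBScan:
    """Complex depth-resolved field, depth bin x A-line.

    Real and imaginary parts are the in-phase and quadrature components
    used by the Kasai autocorrelation estimator.  ``depth_axis_um`` is the
    air-equivalent one-way optical path per depth bin (positive-depth half
    of the padded FFT).
    """

    field: np.ndarray
    depth_axis_um: np.ndarray
    line_period_us: float

    @property
    def n_alines(self) -> int:
        return self.field.shape[1]


@dataclass
class StructuralImage:
    """Log-magnitude structural image in dB, clipped to a display range."""

    log_magnitude_db: np.ndarray
    floor_db: float
    ceiling_db: float


def subtract_background(
    frame: SpectralFrame, background: np.ndarray | None = None
) -> SpectralFrame:
    """Remove the non-interferometric (DC) spectrum from every A-line.

    With ``background=None`` the per-pixel mean across A-lines is
    subtracted — the standard choice for laterally scanned frames, where
    structure decorrelates across the frame.  For non-scanned (M-mode
    style) acquisitions that mean contains the signal itself, so an
    explicit calibration background (e.g. a reference-arm-only spectrum)
    can be supplied instead.
    """
    if background is None:
        if frame.n_alines < 2:
            raise ValueError("frame mean background needs at least 2 A-lines")
        background = frame.spectra.mean(axis=1)
    background = np.asarray(background, dtype=float)
    if background.shape != (frame.pixel_count,):
        raise ValueError("background must have one value per camera pixel")
    return replace(frame, spectra=frame.spectra - background[:, None])


def k_linearize(frame: SpectralFrame, kind: str = "cubic") -> SpectralFrame:
    """Resample spectra from the wavelength grid onto a uniform-k grid.

    k = 2*pi/lambda; the target grid is uniform in k with the same
    endpoints and pixel count as the input.  Cubic-spline interpolation by
    default (``kind="linear"`` available).  The output grid is stored as
    the equivalent wavelengths (still strictly increasing).
    """
    if np.any(np.diff(frame.wavelength_nm) <= 0):
        raise ValueError("wavelength grid must be strictly monotone")
    if kind not in ("cubic", "linear"):
        raise ValueError(f"unknown interpolation kind {kind!r}")
    k = 2.0 * np.pi / frame.wavelength_nm  # decreasing
    k_incr = k[::-1]
    y = frame.spectra[::-1, :]
    k_new = np.linspace(k_incr[0], k_incr[-1], k_incr.size)
    if kind == "cubic":
        resampled = CubicSpline(k_incr, y, axis=0)(k_new)
    else:
        resampled = interp1d(k_incr, y, axis=0, kind="linear")(k_new)
    lam_new = (2.0 * np.pi / k_new)[::-1]
    return replace(
        frame, spectra=resampled[::-1, :], wavelength_nm=lam_new, k_uniform=True
    )


def apodize(frame: SpectralFrame, window_name: str = "hann") -> SpectralFrame:
    """Multiply every A-line by a spectral window (sidelobe control)."""
    if window_name == "none":
        return frame
    n = frame.pixel_count
    if window_name == "hann":
        win = np.hanning(n)
    elif window_name == "gaussian":
        from scipy.signal.windows import gaussian

        win = gaussian(n, std=n / 6.0)
    else:
        raise ValueError(f"unknown window {window_name!r}")
    return replace(frame, spectra=frame.spectra * win[:, None])


def _k_step(wavelength_nm: np.ndarray) -> float:
    k = 2.0 * np.pi / wavelength_nm
    dk = np.diff(k[::-1])
    if not np.allclose(dk, dk[0], rtol=1e-6):
        raise ValueError("frame is not uniformly sampled in k")
    return float(dk.mean())


def to_ascans(frame: SpectralFrame, pad_factor: int = DEFAULT_PAD_FACTOR) -> ComplexBScan:
    """FFT each A-line along the pixel axis into a complex depth profile.

    Requires a k-linearized frame.  The transform is orthonormal
    (``norm="ortho"``), zero-padded by ``pad_factor``, and keeps the
    positive-depth half.  The spectral phase is re-referenced to the
    centre of the k grid, so the phase of a reconstructed peak is
    2 * k_centre * (optical path) — the reference that makes adjacent
    A-line phase differences proportional to displacement at the source's
    band-centre wavelength.
    """
    if not frame.k_uniform:
        raise ValueError("frame must be k-linearized before the depth FFT")
    dk = _k_step(frame.wavelength_nm)  # rad/nm
    n_pix = frame.pixel_count
    n_fft = pad_factor * n_pix
    # pixel axis ordered by increasing k for a positive-depth convention
    x = frame.spectra[::-1, :]
    field = np.fft.fft(x, n=n_fft, axis=0, norm="ortho")
    half = n_fft // 2
    field = field[:half, :]
    # re-reference phase to the central k sample
    m = np.arange(half)
    field = field * np.exp(2j * np.pi * ((n_pix - 1) / 2.0) * m / n_fft)[:, None]
    depth_nm = np.pi * m / (n_fft * dk)
    return ComplexBScan(
        field=field,
        depth_axis_um=depth_nm * 1e-3,
        line_period_us=frame.line_period_us,
    )


def depth_axis_for(
    wavelength_nm: np.ndarray, pad_factor: int = DEFAULT_PAD_FACTOR
) -> np.ndarray:
    """Depth axis (um) that ``to_ascans`` will produce for this grid.

    Accepts either a wavelength-uniform grid (pre-k-linearization) or a
    k-uniform one; the k endpoints, which set the axis, are identical.
    """
    k = 2.0 * np.pi / np.asarray(wavelength_nm, dtype=float)
    n_pix = k.size
    dk = abs(k[-1] - k[0]) / (n_pix - 1)
    n_fft = pad_factor * n_pix
    return np.pi * np.arange(n_fft // 2) / (n_fft * dk) * 1e-3


def log_magnitude(
    bscan: ComplexBScan,
    floor_db: float | None = None,
    ceiling_db: float | None = None,
) -> StructuralImage:
    """20*log10 magnitude image, clipped to [floor, ceiling] for display.

    A small offset (1e-12 of the peak magnitude) keeps the log finite on
    empty pixels.  Defaults: ceiling at the image peak, floor 60 dB below.
    """
    mag = np.abs(bscan.field)
    peak = mag.max()
    eps = LOG_EPS_REL * peak if peak > 0 else LOG_EPS_REL
    db = 20.0 * np.log10(mag + eps)
    if ceiling_db is None:
        ceiling_db = float(db.max())
    if floor_db is None:
        floor_db = ceiling_db - 60.0
    if floor_db >= ceiling_db:
        raise ValueError("floor_db must be below ceiling_db")
    return StructuralImage(
        log_magnitude_db=np.clip(db, floor_db, ceiling_db),
        floor_db=float(floor_db),
        ceiling_db=float(ceiling_db),
    )
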