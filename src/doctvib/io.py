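"""Array-container I/O and image export.

Each pipeline stage persists to a single NumPy ``.npz`` archive with
named arrays plus, where parameters exist, a YAML text sidecar.  Images
export as 16-bit grayscale TIFF (structural) and bidirectional-colormap
PNG (Doppler); response tables as CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .spectral import ComplexBScan, SpectralFrame, StructuralImage
from .vibrometry import FrequencyResponse

__all__ = [
    "save_frame",
    "load_frame",
    "save_bscan",
    "load_bscan",
    "save_structural_tiff",
    "save_doppler_png",
    "response_table",
    "save_response_csv",
    "save_response_plot",
    "write_manifest",
]


def save_frame(frame: SpectralFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        spectra=frame.spectra,
        wavelength_nm=frame.wavelength_nm,
        timestamp_us=frame.timestamp_us,
        line_period_us=np.float64(frame.line_period_us),
        k_uniform=np.bool_(frame.k_uniform),
    )
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(yaml.safe_dump(params, sort_keys=True))


def load_frame(path: str | Path) -> SpectralFrame:
    with np.load(path) as z:
        return SpectralFrame(
            spectra=z["spectra"],
            wavelength_nm=z["wavelength_nm"],
            timestamp_us=z["timestamp_us"],
            line_period_us=float(z["line_period_us"]),
            k_uniform=bool(z["k_uniform"]),
        )


def save_bscan(bscan: ComplexBScan, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        field_real=bscan.field.real,
        field_imag=bscan.field.imag,
        depth_axis_um=bscan.depth_axis_um,
        line_period_us=np.float64(bscan.line_period_us),
    )


def load_bscan(path: str | Path) -> ComplexBScan:
    with np.load(path) as z:
        return ComplexBScan(
            field=z["field_real"] + 1j * z["field_imag"],
            depth_axis_um=z["depth_axis_um"],
            line_period_us=float(z["line_period_us"]),
        )


def save_structural_tiff(structural: StructuralImage, path: str | Path) -> None:
    """16-bit grayscale TIFF mapping [floor, ceiling] dB onto [0, 65535]."""
    span = structural.ceiling_db - structural.floor_db
    norm = (structural.log_magnitude_db - structural.floor_db) / span
    tifffile.imwrite(Path(path), (norm * 65535).astype(np.uint16))


def save_doppler_png(
    phase: np.ndarray,
    path: str | Path,
    vmax_rad: float = np.pi,
    mask: np.ndarray | None = None,
) -> None:
    """Bidirectional Doppler color map: negative blue, positive red/magenta.

    Writes a JSON text sidecar stating the rad-per-level scaling.
    """
    x = np.clip(phase / vmax_rad, -1.0, 1.0)
    pos, neg = np.clip(x, 0, 1), np.clip(-x, 0, 1)
    rgb = np.zeros(phase.shape + (3,))
    rgb[..., 0] = pos  # red
    rgb[..., 2] = neg + 0.5 * pos  # blue for negatives, magenta tint on positives
    if mask is not None:
        rgb[~mask] = 0.0
    Image.fromarray((rgb * 255).astype(np.uint8), mode="RGB").save(Path(path))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "units": "radians",
                "vmax_rad": float(vmax_rad),
                "rad_per_8bit_level": float(vmax_rad / 255.0),
                "positive": "red/magenta (motion away from sample arm)",
                "negative": "blue (motion toward sample arm)",
            },
            indent=2,
        )
    )


def response_table(response: FrequencyResponse) -> pd.DataFrame:
    rows = []
    ctrl_sub = response.means_ctrl_sub
    for ri, label in enumerate(response.roi_labels):
        for fi, f in enumerate(response.frequencies_hz):
            rows.append(
                {
                    "roi_label": label,
                    "frequency_hz": float(f),
                    "mean_rad": response.means[ri, fi],
                    "mean_ctrl_sub_rad": (
                        ctrl_sub[ri, fi] if ctrl_sub is not None else np.nan
                    ),
                    "min_rad": response.spread_low[ri, fi],
                    "max_rad": response.spread_high[ri, fi],
                }
            )
    return pd.DataFrame(rows)


def save_response_csv(response: FrequencyResponse, path: str | Path) -> None:
    response_table(response).to_csv(Path(path), index=False, float_format="%.10g")


def save_response_plot(response: FrequencyResponse, path: str | Path) -> None:
    """Line plot of control-subtracted ROI means with min/max error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    f_khz = response.frequencies_hz / 1000.0
    ctrl = response.means[:, response.control_column()][:, None]
    for ri, label in enumerate(response.roi_labels):
        y = (
            response.means_ctrl_sub[ri]
            if response.means_ctrl_sub is not None
            else response.means[ri]
        )
        yerr = np.vstack(
            [
                response.means[ri] - response.spread_low[ri],
                response.spread_high[ri] - response.means[ri],
            ]
        )
        ax.errorbar(f_khz, y, yerr=yerr, marker="o", capsize=3, label=label)
    del ctrl
    ax.set_xlabel("stimulus frequency (kHz)")
    ax.set_ylabel("control-subtracted mean |Δφ| (rad)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, meta: dict, manifest_name: str = "manifest.json"
) -> Path:
    """Checksum every file under ``out_dir`` into a JSON manifest."""
    out_dir = Path(out_dir)
    files = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != manifest_name
    }
    manifest = dict(meta, files=files)
    path = out_dir / manifest_name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
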