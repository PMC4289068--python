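"""File formats: calibrated TIFF stacks, CSV tables, YAML sidecars.

Stacks and kymographs travel as multi-page grayscale TIFF plus a
sidecar YAML holding the physical calibration (pixel size in µm, frame
interval in s) and the intensity scale used for integer quantization.
Geometry and measurement tables are CSV, always in µm and seconds with
0-based frame indices, x rightward and y downward.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ImageStack, Kymograph
from .contours import Contour, ContourSeries

__all__ = [
    "CalibrationError",
    "read_stack",
    "write_stack",
    "read_kymograph",
    "write_kymograph",
    "write_contour_series",
    "read_contour_series",
    "write_events",
    "binarize_xyt",
]


class CalibrationError(ValueError):
    """Raised when pixel size or frame interval cannot be determined."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        return {}
    with open(sc) as fh:
        return yaml.safe_load(fh) or {}


def write_stack(stack: ImageStack, path: str | Path, bits: int = 16) -> Path:
    """Write a stack as multi-page TIFF (8- or 16-bit) + YAML sidecar.

    Intensities are quantized over [0, intensity_scale] where the scale
    is the data maximum; the scale is recorded in the sidecar so that
    :func:`read_stack` restores the physical values (up to quantization).
    """
    path = Path(path)
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    scale = float(stack.data.max())
    if scale <= 0:
        scale = 1.0
    dtype_max = 2**bits - 1
    raw = np.round(np.clip(stack.data, 0, scale) / scale * dtype_max)
    raw = raw.astype(np.uint8 if bits == 8 else np.uint16)
    tifffile.imwrite(path, raw, photometric="minisblack")
    _write_sidecar(path, dict(
        pixel_size_um=float(stack.pixel_size),
        frame_interval_s=float(stack.frame_interval),
        intensity_scale=scale,
    ))
    return path


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into a calibrated float stack.

    Calibration comes from the YAML sidecar; explicit arguments
    override it. Missing calibration is a hard error. Integer data are
    normalized by the dtype maximum and rescaled by the sidecar's
    ``intensity_scale`` (default 1), so 8- and 16-bit files carry the
    same physical content.
    """
    path = Path(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None, ...]
    if raw.ndim != 3:
        raise ValueError(f"expected grayscale pages, got array of shape {raw.shape}")
    meta = _read_sidecar(path)
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise CalibrationError(
            f"no calibration for {path.name}: provide a YAML sidecar or "
            "explicit pixel_size/frame_interval"
        )
    data = raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        data /= np.iinfo(raw.dtype).max
        data *= float(meta.get("intensity_scale", 1.0))
    return ImageStack(data, float(px), float(dt))


def write_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    """Write a kymograph as float32 TIFF + sidecar (also CSV-able)."""
    path = Path(path)
    tifffile.imwrite(path, kymo.values.astype(np.float32),
                     photometric="minisblack")
    _write_sidecar(path, dict(
        spacing_um=float(kymo.spacing_um),
        spacing_s=float(kymo.spacing_s),
        periodic=bool(kymo.periodic),
    ))
    return path


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    if "spacing_um" not in meta or "spacing_s" not in meta:
        raise CalibrationError(f"no calibration sidecar for kymograph {path.name}")
    return Kymograph(values, meta["spacing_um"], meta["spacing_s"],
                     bool(meta.get("periodic", False)))


def write_contour_series(series: ContourSeries, path: str | Path) -> Path:
    """CSV with columns frame, time_s, point_index, x_um, y_um."""
    rows = []
    for frame, t, contour in series:
        for i, (x, y) in enumerate(contour.points):
            rows.append((frame, t, i, x, y))
    df = pd.DataFrame(rows, columns=["frame", "time_s", "point_index", "x_um", "y_um"])
    df.to_csv(path, index=False)
    return Path(path)


def read_contour_series(
    path: str | Path,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> ContourSeries:
    df = pd.read_csv(path)
    frames, times, contours = [], [], []
    for frame, group in df.groupby("frame", sort=True):
        group = group.sort_values("point_index")
        frames.append(int(frame))
        times.append(float(group["time_s"].iloc[0]))
        contours.append(Contour(group[["x_um", "y_um"]].to_numpy()))
    return ContourSeries(frames, times, contours, pixel_size, frame_interval)


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    events.to_csv(path, index=False)
    return Path(path)


def binarize_xyt(
    stack: ImageStack,
    threshold: float | str = "otsu",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold a stack into a binary x-y-t volume (waves = True).

    Wave pixels are below the threshold (dark fronts). ``mask`` (2-D,
    H×W, True = artifact) zeroes known artifact regions in every frame,
    replacing interactive cleanup. The result is suitable for writing
    as an 8-bit TIFF for external x-y-t iso-surface rendering.
    """
    from skimage.filters import threshold_otsu

    thr = float(threshold_otsu(stack.data)) if threshold == "otsu" else float(threshold)
    binary = stack.data < thr
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.data.shape[1:]:
            raise ValueError(
                f"mask shape {mask.shape} does not match frame shape "
                f"{stack.data.shape[1:]}"
            )
        binary &= ~mask[None, :, :]
    return binary
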