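"""Calibrated array containers shared across the pipeline.

All spatial quantities are in micrometres (µm), time in seconds (s).
Image convention: pixel centres sit at integer indices, origin top-left,
x increases to the right (columns), y downward (rows). Wavefronts are
intensity *minima* on a bright background, as in phase contrast.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A time-lapse stack of grayscale frames with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Intensity values, float. Background is of order 1 for phantoms.
    pixel_size : float
        Lateral calibration, µm per pixel.
    frame_interval : float
        Time between consecutive frames, s.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (T, H, W)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def times(self) -> np.ndarray:
        """Acquisition time of each frame, s."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class Kymograph:
    """Intensity sampled along a fixed spatial path versus time.

    ``values`` is indexed [space, time]. The space axis may be periodic
    (circular sampling paths), in which case position wraps at
    ``n_space * spacing_um``.
    """

    values: np.ndarray
    spacing_um: float
    spacing_s: float
    periodic: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be 2-D (space, time)")
        if self.spacing_um <= 0 or self.spacing_s <= 0:
            raise ValueError("kymograph spacings must be positive")

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def length_um(self) -> float:
        """Extent of the space axis (the period, if periodic)."""
        return self.n_space * self.spacing_um


@dataclass
class CorrelationMap:
    """Normalized spatiotemporal autocorrelation c(Δs, Δt) of a kymograph.

    ``values`` is indexed [Δs, Δt] with zero lag at the centre of each
    axis; ``lags_um`` / ``lags_s`` give the physical lag coordinates.
    c(0, 0) == 1 and c(Δs, Δt) == c(−Δs, −Δt).
    """

    values: np.ndarray
    lags_um: np.ndarray
    lags_s: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lags_um = np.asarray(self.lags_um, dtype=float)
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        if self.values.shape != (self.lags_um.size, self.lags_s.size):
            raise ValueError("lag axes inconsistent with value array")

    @property
    def spacing_um(self) -> float:
        return float(self.lags_um[1] - self.lags_um[0])

    @property
    def spacing_s(self) -> float:
        return float(self.lags_s[1] - self.lags_s[0])
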