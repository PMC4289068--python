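"""Closed-contour geometry: containers, resampling, and smoothing.

A :class:`Contour` is an ordered closed polygon in µm. Orientation is
normalized to counter-clockwise (positive shoelace area in the stored
x/y algebra) on construction so that outward normals — and hence the
sign of normal velocities — are well defined everywhere downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from shapely.geometry import LinearRing


class ContourError(ValueError):
    """Raised for degenerate or invalid contour geometry."""


@dataclass
class Contour:
    """Ordered closed polygon, vertices in µm.

    The closing edge from the last point back to the first is implicit:
    ``points`` never repeats the first vertex.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must have shape (N, 2)")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ContourError("a closed contour needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ContourError("contour points must be finite")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def signed_area(self) -> float:
        """Shoelace area, µm²; positive by the orientation invariant."""
        return _signed_area(self.points)

    def perimeter(self) -> float:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def edge_lengths(self) -> np.ndarray:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def is_simple(self) -> bool:
        """True when the polygon does not self-intersect."""
        try:
            return bool(LinearRing(self.points).is_simple)
        except Exception:
            return False

    def normals(self) -> np.ndarray:
        """Unit outward normal at each vertex.

        The tangent at vertex i is the central difference of its
        neighbours (wrap-around); for a counter-clockwise polygon the
        outward normal is the tangent rotated by −90°: (t_y, −t_x).
        """
        tang = np.roll(self.points, -1, axis=0) - np.roll(self.points, 1, axis=0)
        norm = np.column_stack([tang[:, 1], -tang[:, 0]])
        mag = np.hypot(norm[:, 0], norm[:, 1])
        mag[mag == 0] = 1.0
        return norm / mag[:, None]


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class ContourSeries:
    """One tracked wave: at most one contour per frame, indices increasing."""

    frames: list[int]
    times: list[float]
    contours: list[Contour]
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.times) == len(self.contours)):
            raise ValueError("frames, times and contours must align")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(zip(self.frames, self.times, self.contours))


def resample_contour(contour: Contour, spacing: float = 0.8) -> Contour:
    """Redistribute vertices at equal arc-length spacing.

    The point count becomes ``round(perimeter / spacing)`` and the first
    vertex is preserved, so repeated resampling is (nearly) idempotent.

    Parameters
    ----------
    spacing : float
        Target adjacent-point distance, µm. The default matches a 10x
        objective's resolution limit.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    perim = contour.perimeter()
    if perim < 3 * spacing:
        raise ContourError(
            f"perimeter {perim:.3g} µm too short for spacing {spacing:g} µm"
        )
    n = int(round(perim / spacing))
    closed = np.vstack([contour.points, contour.points[:1]])
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(closed, axis=0).T))])
    targets = np.linspace(0.0, perim, n, endpoint=False)
    new = np.column_stack(
        [np.interp(targets, arc, closed[:, 0]), np.interp(targets, arc, closed[:, 1])]
    )
    return Contour(new)


def smooth_contour(contour: Contour, kernel_width: float) -> Contour:
    """Low-pass filter the x/y coordinate sequences along the contour.

    A normalized Gaussian kernel of standard deviation ``kernel_width``
    (µm, converted to points through the local mean spacing) is applied
    with circular wrap-around, suppressing vertex-scale jitter while
    leaving features larger than the kernel essentially untouched.
    ``kernel_width -> 0`` is the identity.
    """
    if kernel_width < 0:
        raise ValueError("kernel_width must be non-negative")
    if kernel_width == 0:
        return Contour(contour.points.copy())
    mean_spacing = contour.perimeter() / len(contour)
    sigma_pts = kernel_width / mean_spacing
    if sigma_pts < 1e-6:
        return Contour(contour.points.copy())
    half = max(1, int(np.ceil(4 * sigma_pts)))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_pts) ** 2)
    kernel /= kernel.sum()
    n = len(contour)
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    new = np.einsum("ijk,j->ik", contour.points[idx], kernel)
    return Contour(new)
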