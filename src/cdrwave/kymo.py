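"""Linear and circular kymographs, ROI traces, recovery times, R_max.

A kymograph samples image intensity along a fixed path — a straight
line through a wave origin, or a circle around the nucleus of a
disk-shaped cell — for every frame, yielding a space × time map in
which propagating fronts appear as sloped dark stripes. Oscillatory
re-appearing waves show up in ROI minimum-intensity traces as negative
peaks separated by bright plateaus (the recovery time τ).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ImageStack, Kymograph

__all__ = [
    "IntensityTrace",
    "BoxBinSummary",
    "linear_kymograph",
    "circular_kymograph",
    "roi_min_trace",
    "recovery_times",
    "rmax_from_kymograph",
    "bin_tau_by_rmax",
]


def _sample_frames(stack: ImageStack, cols_px: np.ndarray, rows_px: np.ndarray) -> np.ndarray:
    """Bilinear samples of every frame at the given pixel path."""
    out = np.empty((len(cols_px), stack.n_frames))
    coords = np.vstack([rows_px, cols_px])
    for k in range(stack.n_frames):
        out[:, k] = ndimage.map_coordinates(stack.data[k], coords, order=1)
    return out


def linear_kymograph(
    stack: ImageStack,
    start_um: tuple[float, float],
    end_um: tuple[float, float],
) -> Kymograph:
    """Sample intensity along a straight line per frame.

    Steps along the line equal one pixel size. Both endpoints must lie
    inside the frame.
    """
    p0 = np.asarray(start_um, dtype=float)
    p1 = np.asarray(end_um, dtype=float)
    dist = float(np.hypot(*(p1 - p0)))
    if dist <= 0:
        raise ValueError("line endpoints coincide")
    _, h, w = stack.shape
    px = stack.pixel_size
    for p in (p0, p1):
        if not (0 <= p[0] <= (w - 1) * px and 0 <= p[1] <= (h - 1) * px):
            raise ValueError("line endpoint outside the frame")
    n = int(np.floor(dist / px)) + 1
    direction = (p1 - p0) / dist
    positions = p0[None, :] + np.arange(n)[:, None] * px * direction
    values = _sample_frames(stack, positions[:, 0] / px, positions[:, 1] / px)
    return Kymograph(values, spacing_um=px, spacing_s=stack.frame_interval,
                     periodic=False)


def circular_kymograph(
    stack: ImageStack,
    center_um: tuple[float, float],
    radius_um: float,
) -> Kymograph:
    """Sample intensity along a circle per frame (periodic space axis).

    Arc-length steps equal one pixel size (the sampling circle is
    discretized into round(2πr/pixel) points), so the space axis wraps
    with period 2πr.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center_um
    _, h, w = stack.shape
    px = stack.pixel_size
    if (cx - radius_um < 0 or cy - radius_um < 0
            or cx + radius_um > (w - 1) * px or cy + radius_um > (h - 1) * px):
        raise ValueError("sampling circle exits the frame")
    n = max(8, int(round(2 * np.pi * radius_um / px)))
    ang = 2 * np.pi * np.arange(n) / n
    xs = cx + radius_um * np.cos(ang)
    ys = cy + radius_um * np.sin(ang)
    values = _sample_frames(stack, xs / px, ys / px)
    return Kymograph(values, spacing_um=2 * np.pi * radius_um / n,
                     spacing_s=stack.frame_interval, periodic=True)


@dataclass
class IntensityTrace:
    """Minimum-intensity time series of a smoothed ROI."""

    values: np.ndarray
    frame_interval: float

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


def roi_min_trace(
    stack: ImageStack,
    roi_um: tuple[float, float, float, float],
    gaussian_sigma_um: float = 2.0,
) -> IntensityTrace:
    """Per-frame minimum intensity of a Gaussian-smoothed ROI.

    ``roi_um`` is (x0, y0, x1, y1) in µm. The ROI is smoothed with a
    Gaussian of σ = ``gaussian_sigma_um`` (2 µm by default) before the
    minimum is taken, suppressing single-pixel noise minima.
    """
    x0, y0, x1, y1 = roi_um
    px = stack.pixel_size
    c0, c1 = sorted((int(round(x0 / px)), int(round(x1 / px))))
    r0, r1 = sorted((int(round(y0 / px)), int(round(y1 / px))))
    _, h, w = stack.shape
    c0, c1 = max(c0, 0), min(c1 + 1, w)
    r0, r1 = max(r0, 0), min(r1 + 1, h)
    if c1 - c0 < 1 or r1 - r0 < 1:
        raise ValueError("empty ROI")
    sigma_px = gaussian_sigma_um / px
    vals = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        sub = stack.data[k, r0:r1, c0:c1]
        if sigma_px > 0:
            sub = ndimage.gaussian_filter(sub, sigma_px, mode="nearest")
        vals[k] = sub.min()
    return IntensityTrace(vals, stack.frame_interval)


def default_event_threshold(values: np.ndarray) -> float:
    """Midpoint between the trace median (baseline) and its minimum."""
    return 0.5 * (float(np.median(values)) + float(values.min()))


def recovery_times(
    trace: IntensityTrace,
    event_threshold: float | None = None,
) -> list[float]:
    """Quiescent intervals τ between successive wave events, seconds.

    Events are maximal runs of the trace below the threshold; τ spans
    from the frame after one event ends to the onset frame of the next.
    Fewer than two events yields an empty list (with a warning).
    """
    v = trace.values
    thr = default_event_threshold(v) if event_threshold is None else event_threshold
    below = v < thr
    starts = list(np.flatnonzero(below & ~np.roll(below, 1)))
    ends = list(np.flatnonzero(below & ~np.roll(below, -1)))
    if below[0]:  # np.roll wraps; a run starting at index 0 has no predecessor
        starts = sorted(set(starts) | {0})
    if below[-1]:
        ends = sorted(set(ends) | {len(v) - 1})
    if len(starts) < 2:
        warnings.warn("fewer than two events in trace; no recovery times",
                      stacklevel=2)
        return []
    taus = []
    for e, s_next in zip(ends[:-1], starts[1:]):
        taus.append(max(0.0, (s_next - e - 1) * trace.frame_interval))
    return taus


def rmax_from_kymograph(
    kymo: Kymograph,
    threshold: float | None = None,
) -> list[float]:
    """Maximal radial extension R_max per wave event, µm.

    For a linear kymograph sampled along a line through the wave
    origin, each event's dark trace spans ±R_max about the origin; the
    estimate is half the maximal spatial extent of each connected dark
    component, events ordered by onset time.
    """
    from skimage.filters import threshold_otsu

    v = kymo.values
    thr = threshold if threshold is not None else float(threshold_otsu(v))
    binary = v < thr
    if not binary.any():
        return []
    labels, n = ndimage.label(binary)
    results = []
    for lab in range(1, n + 1):
        component = labels == lab
        cols = np.nonzero(component.any(axis=0))[0]
        best = 0.0
        for col in cols:
            rows = np.nonzero(component[:, col])[0]
            breaks = np.flatnonzero(np.diff(rows) > 1)
            runs = np.split(rows, breaks + 1)
            if len(runs) >= 2:
                # two branches: distance between their centrelines
                lo = (runs[0][0] + runs[0][-1]) / 2.0
                hi = (runs[-1][0] + runs[-1][-1]) / 2.0
                extent = (hi - lo) / 2.0
            else:
                # unsplit trace: half its width on each side of the origin
                extent = (rows.max() - rows.min()) / 4.0
            best = max(best, extent * kymo.spacing_um)
        results.append((cols.min(), best))
    results.sort()
    return [r for _, r in results]


@dataclass
class BoxBinSummary:
    """Box statistics of recovery time τ binned by wave size R_max."""

    bin_edges: np.ndarray     # µm
    median: np.ndarray        # s; NaN for empty bins
    q25: np.ndarray
    q75: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                rmax_lo=self.bin_edges[:-1],
                rmax_hi=self.bin_edges[1:],
                tau_median=self.median,
                tau_q25=self.q25,
                tau_q75=self.q75,
                n=self.counts,
            )
        )


def bin_tau_by_rmax(
    pairs: list[tuple[float, float]],
    bin_width: float = 10.0,
) -> BoxBinSummary:
    """Bin (R_max, τ) pairs in R_max with the given box width (µm)."""
    if not pairs:
        raise ValueError("no (R_max, tau) pairs supplied")
    rmax = np.array([p[0] for p in pairs], dtype=float)
    tau = np.array([p[1] for p in pairs], dtype=float)
    top = np.ceil(rmax.max() / bin_width) * bin_width
    edges = np.arange(0.0, max(top, bin_width) + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(rmax, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    median = np.full(n_bins, np.nan)
    q25 = np.full(n_bins, np.nan)
    q75 = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            median[b] = np.median(tau[sel])
            q25[b], q75[b] = np.percentile(tau[sel], [25, 75])
    return BoxBinSummary(edges, median, q25, q75, counts)
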