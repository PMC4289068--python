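"""Per-point wavefront kinematics and the velocity–area collapse.

Normal velocity follows the ray-casting definition: from each vertex of
the contour at time t a ray is cast along the local outward normal and
intersected with the (linearly interpolated) contour at t+Δt; signed
distance over Δt is the local velocity, positive for outward growth.

The mean velocity of an opening wave collapses, when plotted against
the normalized enclosed area a = A/A_max, onto the closed form implied
by a parabolic radius evolution R(t) = v0·t − v0/(2·t_rev)·t²:

    a(v) = (1 − (v/v0)²)²   ⇔   v(a) = v0·√(1 − √a)

which is the unique quartic consistent with that law. Fitting this form
to the binned collapse and evaluating it at a = 0 extrapolates the
initial wavefront speed v0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy import optimize, stats

from .contours import Contour, ContourSeries

__all__ = [
    "KinematicsRecord",
    "VelocityAreaCurve",
    "ExtrapolationResult",
    "local_normal_velocity",
    "local_curvature",
    "enclosed_area",
    "series_kinematics",
    "velocity_area_collapse",
    "fit_extrapolate_v0",
    "curvature_velocity_correlation",
]


class KinematicsError(ValueError):
    pass


def local_normal_velocity(
    c_t: Contour,
    c_next: Contour,
    dt: float,
    cutoff: float = 5.0,
) -> np.ndarray:
    """Signed normal velocity at every vertex of ``c_t``, µm/s.

    A bidirectional ray along the outward normal of each vertex is
    intersected with every edge of ``c_next``; the nearest intersection
    within ``cutoff`` µm wins (ties broken toward the outward side).
    Positive velocity means outward motion (wave growth). Vertices with
    no intersection are returned as NaN.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = c_t.points                      # (N, 2)
    n = c_t.normals()                   # (N, 2)
    q = c_next.points                   # (M, 2)
    e = np.roll(q, -1, axis=0) - q      # (M, 2) edge vectors

    w = q[None, :, :] - p[:, None, :]   # (N, M, 2)
    cross_ne = n[:, None, 0] * e[None, :, 1] - n[:, None, 1] * e[None, :, 0]
    cross_we = w[:, :, 0] * e[None, :, 1] - w[:, :, 1] * e[None, :, 0]
    cross_wn = w[:, :, 0] * n[:, None, 1] - w[:, :, 1] * n[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = cross_we / cross_ne          # distance along the normal
        u = cross_wn / cross_ne          # position along the edge
    # small tolerance so rays through a vertex of c_next (u ~ 0 or 1) hit
    valid = ((np.abs(cross_ne) > 1e-12) & (u >= -1e-9) & (u <= 1 + 1e-9)
             & (np.abs(d) <= cutoff))
    d = np.where(valid, d, np.nan)
    # nearest |d|; ties toward outward (positive d) by an infinitesimal bias
    rank = np.abs(d) - 1e-9 * np.sign(d)
    velocities = np.full(len(p), np.nan)
    has = ~np.all(np.isnan(rank), axis=1)
    idx = np.nanargmin(np.where(np.isnan(rank), np.inf, rank), axis=1)
    velocities[has] = d[np.arange(len(p)), idx][has] / dt
    if not has.any():
        raise KinematicsError("no ray intersections found; contours unrelated")
    return velocities


def local_curvature(contour: Contour, window: float = 2.4) -> np.ndarray:
    """Signed local curvature (1/µm) from circumscribed circles.

    Each vertex and its neighbours ±``window`` µm of arc length define
    a circle whose inverse radius (Menger curvature) is the estimate;
    positive where the contour is convex with respect to the outward
    normal.
    """
    spacing = contour.perimeter() / len(contour)
    if window < spacing:
        raise KinematicsError(
            f"curvature window {window:g} µm below vertex spacing {spacing:g} µm"
        )
    w = max(1, int(round(window / spacing)))
    p0 = np.roll(contour.points, w, axis=0)
    p1 = contour.points
    p2 = np.roll(contour.points, -w, axis=0)
    v1 = p1 - p0
    v2 = p2 - p1
    v3 = p2 - p0
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    denom = (np.hypot(*v1.T) * np.hypot(*v2.T) * np.hypot(*v3.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return kappa


def enclosed_area(contour: Contour) -> float:
    """Shoelace area in µm² (positive; contours are counter-clockwise)."""
    area = contour.signed_area()
    if abs(area) < 1e-12:
        centered = contour.points - contour.points.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            return 0.0  # degenerate collinear polygon
        raise KinematicsError("zero-area self-intersecting contour")
    if not contour.is_simple():
        raise KinematicsError("contour is self-intersecting; area undefined")
    return area


@dataclass
class KinematicsRecord:
    """Per-frame kinematic measurements of one tracked wave."""

    frame: int
    time_s: float
    velocities: np.ndarray | None   # µm/s, NaN where the ray missed
    curvatures: np.ndarray          # 1/µm
    mean_velocity: float            # µm/s (NaN on the last frame)
    area_um2: float
    normalized_area: float = np.nan


def series_kinematics(
    series: ContourSeries,
    curvature_window: float = 2.4,
    cutoff: float = 5.0,
) -> list[KinematicsRecord]:
    """Velocities, curvatures, areas and normalized areas per frame.

    Velocity at frame k is measured against frame k+1, so the final
    record carries area and curvature only (mean velocity NaN).
    Normalized area is A/A_max with A_max taken over this series'
    tracked lifetime.
    """
    if len(series) < 2:
        raise KinematicsError("need at least 2 frames for kinematics")
    records: list[KinematicsRecord] = []
    areas = np.array([enclosed_area(c) for c in series.contours])
    a_max = areas.max()
    if a_max <= 0:
        raise KinematicsError("all contours degenerate")
    for i, (frame, t, c) in enumerate(series):
        if i + 1 < len(series):
            dt = series.times[i + 1] - t
            vel = local_normal_velocity(c, series.contours[i + 1], dt, cutoff)
            vbar = float(np.nanmean(vel))
        else:
            vel, vbar = None, np.nan
        records.append(
            KinematicsRecord(
                frame=frame,
                time_s=t,
                velocities=vel,
                curvatures=local_curvature(c, curvature_window),
                mean_velocity=vbar,
                area_um2=float(areas[i]),
                normalized_area=float(areas[i] / a_max),
            )
        )
    return records


@dataclass
class VelocityAreaCurve:
    """Pooled (a, v̄) points and their box-median binning (width 0.05)."""

    raw_a: np.ndarray
    raw_v: np.ndarray
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_median: np.ndarray   # NaN for empty bins
    bin_count: np.ndarray


def velocity_area_collapse(
    record_sets: list[list[KinematicsRecord]],
    bin_width: float = 0.05,
) -> VelocityAreaCurve:
    """Pool opening-phase mean velocities over waves and bin in a.

    Opening phase means frames before each wave's maximal area. Binned
    statistic is the median within boxes of width ``bin_width`` tiling
    [0, 1].
    """
    if not record_sets:
        raise KinematicsError("no kinematics records supplied")
    a_pool, v_pool = [], []
    for records in record_sets:
        areas = np.array([r.area_um2 for r in records])
        i_max = int(np.argmax(areas))
        for r in records[:i_max]:
            if np.isfinite(r.mean_velocity):
                a_pool.append(r.normalized_area)
                v_pool.append(r.mean_velocity)
    if not a_pool:
        raise KinematicsError("no opening-phase points to pool")
    raw_a = np.asarray(a_pool)
    raw_v = np.asarray(v_pool)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    idx = np.clip(np.digitize(raw_a, edges) - 1, 0, len(edges) - 2)
    median = np.full(len(edges) - 1, np.nan)
    count = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            median[b] = float(np.median(raw_v[sel]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VelocityAreaCurve(raw_a, raw_v, edges, centers, median, count)


@dataclass
class ExtrapolationResult:
    """Outcome of the v(a) collapse fit."""

    v0: float               # extrapolated v(a=0), µm/s
    residual_rms: float     # µm/s, over populated bins
    parabolic: bool         # residuals consistent with the parabolic law
    method: str = "closed_form"


def _collapse_model(a: np.ndarray, v0: float) -> np.ndarray:
    return v0 * np.sqrt(np.clip(1.0 - np.sqrt(np.clip(a, 0.0, None)), 0.0, None))


def fit_extrapolate_v0(
    curve: VelocityAreaCurve,
    method: str = "closed_form",
    residual_fraction: float = 0.15,
) -> ExtrapolationResult:
    """Extrapolate the collapse to zero area.

    ``closed_form`` fits v(a) = v0·√(1 − √a), the collapse implied by a
    parabolic radius evolution, by least squares over the populated
    bins; ``quartic`` fits a free fourth-order polynomial instead and
    evaluates it at a = 0. The fit is flagged non-parabolic when the
    RMS residual exceeds ``residual_fraction`` of the fitted v0.
    """
    ok = np.isfinite(curve.bin_median)
    if ok.sum() < 5:
        raise KinematicsError("need at least 5 populated bins to fit")
    a = curve.bin_centers[ok]
    v = curve.bin_median[ok]
    if method == "closed_form":
        p0 = max(v.max(), 1e-6)
        popt, _ = optimize.curve_fit(_collapse_model, a, v, p0=[p0], maxfev=10000)
        v0 = float(popt[0])
        resid = v - _collapse_model(a, v0)
    elif method == "quartic":
        coeffs = np.polyfit(a, v, 4)
        v0 = float(np.polyval(coeffs, 0.0))
        resid = v - np.polyval(coeffs, a)
    else:
        raise ValueError(f"unknown method {method!r}")
    rms = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(v0):
        raise KinematicsError(f"collapse fit did not converge (rms {rms:.3g})")
    return ExtrapolationResult(v0=v0, residual_rms=rms,
                               parabolic=rms <= residual_fraction * abs(v0),
                               method=method)


def curvature_velocity_correlation(
    records: list[KinematicsRecord],
    max_lag: int | None = None,
) -> tuple[float, np.ndarray]:
    """Pearson correlation of pooled per-point (curvature, velocity) pairs.

    Also returns the mean per-contour circular cross-correlation versus
    arc-length lag (in vertex steps), so a spatially shifted coupling
    would still be visible.
    """
    kappa, vel = [], []
    per_contour = []
    for r in records:
        if r.velocities is None:
            continue
        good = np.isfinite(r.velocities)
        if good.sum() < 4:
            continue
        kappa.append(r.curvatures[good])
        vel.append(r.velocities[good])
        per_contour.append((r.curvatures[good], r.velocities[good]))
    if not kappa:
        raise KinematicsError("no finite (curvature, velocity) pairs")
    k_all = np.concatenate(kappa)
    v_all = np.concatenate(vel)
    if len(k_all) < 100:
        raise KinematicsError("need at least 100 pooled pairs")
    if np.std(k_all) < 1e-12 or np.std(v_all) < 1e-12:
        raise KinematicsError("zero variance; correlation undefined")
    r_pool = float(stats.pearsonr(k_all, v_all)[0])

    lags_profiles = []
    for k_c, v_c in per_contour:
        n = len(k_c)
        if np.std(k_c) < 1e-12 or np.std(v_c) < 1e-12:
            continue
        kz = (k_c - k_c.mean()) / k_c.std()
        vz = (v_c - v_c.mean()) / v_c.std()
        m = max_lag if max_lag is not None else n // 2
        prof = np.array([np.mean(kz * np.roll(vz, lag)) for lag in range(-m, m + 1)])
        lags_profiles.append(prof)
    if lags_profiles:
        length = min(len(p) for p in lags_profiles)
        trimmed = [p[(len(p) - length) // 2:(len(p) - length) // 2 + length]
                   for p in lags_profiles]
        lag_profile = np.mean(trimmed, axis=0)
    else:
        lag_profile = np.array([r_pool])
    return r_pool, lag_profile
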