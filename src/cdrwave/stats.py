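"""Spatiotemporal statistics of wave kymographs.

Segmentation, periodic 2-D autocorrelation c(Δs, Δt), Radon-based
extraction of propagation velocities, inter-event periods from temporal
cuts, and detection/classification of wave events (initiations,
annihilations, collisions with terminal gaps, spiral rotations).

The autocorrelation is circular along the space axis (the sampling
circle of a disk cell is periodic) and linear along time with unbiased
edge normalization. Oriented ridges in c(Δs, Δt) encode the propagation
speed; the dominant ridge orientation is found as the projection angle
that maximizes the variance of the Radon transform of the map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.transform import radon

from .containers import CorrelationMap, ImageStack, Kymograph

__all__ = [
    "segment_kymograph",
    "autocorrelation_2d",
    "radon_velocity",
    "average_correlation",
    "cuts",
    "period_from_cut",
    "detect_events",
    "terminal_gap",
    "count_rotations",
    "RadonVelocityResult",
]


def segment_kymograph(
    kymo: Kymograph,
    threshold: float | str = "otsu",
    invert: bool = False,
) -> Kymograph:
    """Binarize a kymograph: wave pixels are intensity *below* threshold.

    ``threshold`` is a number or ``"otsu"``. With ``invert`` the waves
    are taken as maxima instead (e.g. fluorescence data).
    """
    v = kymo.values
    if not np.all(np.isfinite(v)):
        raise ValueError("kymograph contains non-finite values")
    thr = float(threshold_otsu(v)) if threshold == "otsu" else float(threshold)
    binary = (v > thr) if invert else (v < thr)
    if binary.all() or not binary.any():
        warnings.warn("segmentation is all-one or all-zero", stacklevel=2)
    return Kymograph(binary.astype(float), kymo.spacing_um, kymo.spacing_s,
                     kymo.periodic)


def autocorrelation_2d(kymo: Kymograph) -> CorrelationMap:
    """Normalized autocorrelation c(Δs, Δt) of a (binary) kymograph.

    Mean-subtracted and variance-normalized so c(0, 0) = 1 exactly.
    The space axis is treated as circular; the time axis is linear with
    unbiased normalization (each lag divided by its overlap count).
    Holds the point symmetry c(Δs, Δt) = c(−Δs, −Δt).
    """
    f = kymo.values - kymo.values.mean()
    var = float(np.mean(f**2))
    if var <= 0:
        raise ValueError("zero-variance kymograph; autocorrelation undefined")
    s_n, t_n = f.shape
    padded = np.zeros((s_n, 2 * t_n))
    padded[:, :t_n] = f
    spec = np.fft.fft2(padded)
    raw = np.fft.ifft2(spec * np.conj(spec)).real  # sum over valid overlaps
    # reorder time lags to -(t_n-1) .. t_n-1, space lags centered
    t_lags = np.concatenate([np.arange(-(t_n - 1), 0), np.arange(t_n)])
    raw = np.concatenate([raw[:, t_n + 1:], raw[:, :t_n]], axis=1)
    counts = s_n * (t_n - np.abs(t_lags))
    c = raw / counts[None, :] / var
    c = np.fft.fftshift(c, axes=0)
    s_lags = np.fft.fftshift(np.fft.fftfreq(s_n, d=1.0 / s_n)).astype(int)
    return CorrelationMap(
        values=c,
        lags_um=s_lags * kymo.spacing_um,
        lags_s=t_lags * kymo.spacing_s,
        periodic=kymo.periodic,
    )


@dataclass
class RadonVelocityResult:
    """Dominant ridge orientations of a correlation map as velocities."""

    velocities: np.ndarray          # µm/s, signed, one per dominant ridge
    angles_deg: np.ndarray          # corresponding projection angles
    variance_profile: np.ndarray    # projection variance per grid angle
    angle_grid_deg: np.ndarray
    significance_level: float       # permutation 99th percentile

    @property
    def speed(self) -> float:
        """Mean |v| over dominant orientations (one entry per map)."""
        if self.velocities.size == 0:
            return float("nan")
        return float(np.mean(np.abs(self.velocities)))


def _square_center_crop(cmap: CorrelationMap, max_lag_s: float | None):
    """Odd-sized square crop of the map centred on zero lag."""
    vals = cmap.values
    s_n, t_n = vals.shape
    i0 = int(np.argmin(np.abs(cmap.lags_um)))
    j0 = int(np.argmin(np.abs(cmap.lags_s)))
    half_t = (t_n - 1) // 2
    if max_lag_s is not None:
        half_t = min(half_t, int(max_lag_s / cmap.spacing_s))
    half = min(i0, s_n - 1 - i0, j0, t_n - 1 - j0, half_t)
    return vals[i0 - half:i0 + half + 1, j0 - half:j0 + half + 1]


def radon_velocity(
    cmap: CorrelationMap,
    angle_step_deg: float = 0.5,
    significance_ratio: float = 10.0,
    max_lag_s: float | None = None,
) -> RadonVelocityResult:
    """Propagation velocities from ridge orientations of c(Δs, Δt).

    The map is cropped square around zero lag, circularly windowed, and
    Radon-transformed over a grid of projection angles; angles at which
    the projection variance peaks correspond to integration parallel to
    a ridge. A stripe of slope m pixels (Δs) per pixel (Δt) peaks at
    θ = 90° − atan(m), so v = cot(θ)·(Δs spacing)/(Δt spacing). Both
    signs appear for bidirectional propagation. Peak angles are refined
    by parabolic interpolation and count as dominant only when their
    projection variance exceeds ``significance_ratio`` times the median
    variance over all angles — oriented maps exceed this by two orders
    of magnitude while isotropic (noise) maps stay well below it — so
    an isotropic map returns no velocities.
    """
    img = _square_center_crop(cmap, max_lag_s).copy()
    n = img.shape[0]
    if n < 16:
        raise ValueError("correlation map too small for Radon analysis (need >=16)")
    c = n // 2
    # the c(0,0)=1 spike carries no orientation; blank it so it cannot
    # dominate the projection variance
    img[c - 1:c + 2, c - 1:c + 2] = 0.0
    yy, xx = np.indices(img.shape)
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (c - 0.5) ** 2
    win = img * mask

    angles = np.arange(0.0, 180.0, angle_step_deg)
    var_profile = radon(win, theta=angles, circle=True).var(axis=0)
    level = significance_ratio * float(np.median(var_profile))

    peaks = _circular_peaks(var_profile)
    vels, angs = [], []
    px_ratio = cmap.spacing_um / cmap.spacing_s
    for i in peaks:
        if var_profile[i] <= level:
            continue
        theta = _parabolic_refine(angles, var_profile, i)
        m = 1.0 / np.tan(np.deg2rad(theta)) if theta % 180 != 0 else np.inf
        if not np.isfinite(m):
            continue
        vels.append(m * px_ratio)
        angs.append(theta)
    return RadonVelocityResult(
        velocities=np.asarray(vels),
        angles_deg=np.asarray(angs),
        variance_profile=var_profile,
        angle_grid_deg=angles,
        significance_level=level,
    )


def _circular_peaks(profile: np.ndarray, min_separation: int = 5) -> list[int]:
    """Local maxima of a 180°-periodic profile, strongest first."""
    n = len(profile)
    prev = np.roll(profile, 1)
    nxt = np.roll(profile, -1)
    idx = np.flatnonzero((profile >= prev) & (profile > nxt))
    idx = idx[np.argsort(-profile[idx])]
    kept: list[int] = []
    for i in idx:
        if all(min(abs(i - j), n - abs(i - j)) >= min_separation for j in kept):
            kept.append(int(i))
    return kept


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    n = len(x)
    y0, y1, y2 = y[(i - 1) % n], y[i], y[(i + 1) % n]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    step = x[1] - x[0]
    return float(x[i] + np.clip(delta, -1, 1) * step)


def average_correlation(maps: list[CorrelationMap]) -> CorrelationMap:
    """Element-wise mean of correlation maps.

    Maps on different lag grids (different cell circumferences or
    recording lengths) are linearly resampled onto the first map's
    grid, clipped to the overlapping lag range, before averaging.
    """
    from scipy.interpolate import RegularGridInterpolator

    if not maps:
        raise ValueError("no correlation maps to average")
    ref = maps[0]
    same = all(
        m.values.shape == ref.values.shape
        and np.allclose(m.lags_um, ref.lags_um)
        and np.allclose(m.lags_s, ref.lags_s)
        for m in maps[1:]
    )
    if same:
        mean = np.mean([m.values for m in maps], axis=0)
        return CorrelationMap(mean, ref.lags_um.copy(), ref.lags_s.copy(),
                              ref.periodic)
    lo_um = max(m.lags_um.min() for m in maps)
    hi_um = min(m.lags_um.max() for m in maps)
    lo_s = max(m.lags_s.min() for m in maps)
    hi_s = min(m.lags_s.max() for m in maps)
    keep_um = (ref.lags_um >= lo_um) & (ref.lags_um <= hi_um)
    keep_s = (ref.lags_s >= lo_s) & (ref.lags_s <= hi_s)
    grid_um = ref.lags_um[keep_um]
    grid_s = ref.lags_s[keep_s]
    pts = np.stack(np.meshgrid(grid_um, grid_s, indexing="ij"), axis=-1)
    acc = np.zeros((grid_um.size, grid_s.size))
    for m in maps:
        interp = RegularGridInterpolator((m.lags_um, m.lags_s), m.values)
        acc += interp(pts)
    return CorrelationMap(acc / len(maps), grid_um, grid_s, ref.periodic)


def cuts(cmap: CorrelationMap) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Zero-lag cuts: (lags_s, c(0, Δt)) and (lags_um, c(Δs, 0))."""
    i0 = int(np.argmin(np.abs(cmap.lags_um)))
    j0 = int(np.argmin(np.abs(cmap.lags_s)))
    return (cmap.lags_s, cmap.values[i0, :]), (cmap.lags_um, cmap.values[:, j0])


def period_from_cut(lags_s: np.ndarray, c0: np.ndarray) -> float | None:
    """Inter-event period from the temporal autocorrelation cut.

    The period is the lag of the first local maximum of c(0, Δt) after
    the first negative excursion (the quiescent interval); None when no
    such maximum exists.
    """
    pos = lags_s > 0
    lag = lags_s[pos]
    c = np.asarray(c0, dtype=float)[pos]
    if c.size >= 5:  # light smoothing for noise robustness
        kernel = np.array([0.25, 0.5, 0.25])
        c = np.convolve(c, kernel, mode="same")
    neg = np.flatnonzero(c < 0)
    if neg.size == 0:
        return None
    # first positive lobe after the quiescent (negative) interval:
    # its maximum is the inter-event period
    up = neg[0] + np.argmax(c[neg[0]:] > 0)
    if c[up] <= 0:
        return None
    down = up + np.argmax(c[up:] < 0)
    if c[down] >= 0:  # lobe extends to the end of the cut
        down = len(c)
    # lobe centroid: robust to bin-scale noise on a symmetric peak
    weights = np.clip(c[up:down], 0.0, None)
    if weights.sum() <= 0:
        return None
    return float(np.sum(lag[up:down] * weights) / weights.sum())


# ---------------------------------------------------------------------------
# Event detection on segmented kymographs
# ---------------------------------------------------------------------------


@dataclass
class _Track:
    id: int
    t: list[int]
    s: list[float]       # arc position, µm (unwrapped locally per step)
    alive: bool = True
    born_from_split: bool = False

    def slope(self, circ: float | None, k: int = 4) -> float:
        """End slope µm/frame over the last k samples (wrap-aware)."""
        t = self.t[-k:]
        s = self.s[-k:]
        if len(t) < 2:
            return 0.0
        ds = np.diff(s)
        if circ:
            ds = (ds + circ / 2) % circ - circ / 2
        return float(np.sum(ds) / (t[-1] - t[0]))

    def predict(self, circ: float | None) -> float:
        """Expected position one frame ahead (constant-velocity model)."""
        p = self.s[-1] + self.slope(circ)
        return p % circ if circ else p


def _column_runs(col: np.ndarray, periodic: bool) -> list[tuple[float, float]]:
    """(centre index, half-width) of True runs in one kymograph column."""
    n = len(col)
    if not col.any():
        return []
    if col.all():
        return [(n / 2.0, n / 2.0)]
    idx = np.flatnonzero(col)
    # split into consecutive runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    out = [( (r[0] + r[-1]) / 2.0, (r[-1] - r[0] + 1) / 2.0) for r in runs]
    if periodic and len(out) > 1 and col[0] and col[-1]:
        first, last = runs[0], runs[-1]
        merged_len = len(first) + len(last)
        center = (last[0] + (merged_len - 1) / 2.0) % n
        out = out[1:-1] + [(center, merged_len / 2.0)]
    return out


def _wrap_delta(a: float, b: float, circ: float | None) -> float:
    d = a - b
    if circ:
        d = (d + circ / 2) % circ - circ / 2
    return d


def detect_events(
    kymo: Kymograph,
    already_binary: bool = True,
    max_jump_um: float = 6.0,
    pair_window_frames: int = 3,
    pair_window_um: float = 25.0,
    merge_window_frames: int = 12,
) -> pd.DataFrame:
    """Detect and classify wave events in a segmented kymograph.

    Dark-run centres are extracted per time column and linked into
    tracks by nearest-neighbour association (wrap-aware on periodic
    axes). Events:

    * ``initiation`` — a track born away from existing tracks (the apex
      of a "<" in the kymograph; the subsequent split into two
      counter-propagating branches belongs to the same event),
    * ``collision`` / class ``mutual`` — two converging tracks dying
      together, with the terminal front gap recorded,
    * ``collision`` / class ``one_survives`` — converging tracks that
      merge and re-emerge (crossing),
    * ``annihilation`` — an unpaired track death.

    Deaths within the last two columns are attributed to the end of the
    recording, not to events.
    """
    binary = kymo.values > 0.5 if already_binary else segment_kymograph(kymo).values > 0.5
    s_n, t_n = binary.shape
    circ = kymo.length_um if kymo.periodic else None
    ds = kymo.spacing_um
    dt = kymo.spacing_s

    tracks: list[_Track] = []
    next_id = 0
    events: list[dict] = []
    pending_merges: list[dict] = []  # {"t": frame, "s": µm, "survivor": id}
    collided: set[frozenset] = set()  # track-id pairs already classified
    prev_sep: dict[frozenset, float] = {}

    for k in range(t_n):
        runs = _column_runs(binary[:, k], kymo.periodic)
        centers = [c * ds for c, _ in runs]
        active = [tr for tr in tracks if tr.alive]
        # associate runs to active tracks (greedy, against predicted position)
        pairs = []
        for ri, c in enumerate(centers):
            for tr in active:
                d = abs(_wrap_delta(c, tr.predict(circ), circ))
                if d <= max_jump_um:
                    pairs.append((d, ri, tr))
        pairs.sort(key=lambda x: x[0])
        run_taken: dict[int, _Track] = {}
        track_taken: set[int] = set()
        run_extra: dict[int, list[_Track]] = {}
        for d, ri, tr in pairs:
            if ri in run_taken:
                if tr.id not in track_taken:
                    run_extra.setdefault(ri, []).append(tr)
                    track_taken.add(tr.id)
                continue
            if tr.id in track_taken:
                continue
            run_taken[ri] = tr
            track_taken.add(tr.id)
        # continue matched tracks
        for ri, tr in run_taken.items():
            tr.t.append(k)
            tr.s.append(centers[ri])
        # crossings: pairs whose separation changes sign at close approach
        alive_now = [tr for tr in tracks if tr.alive and tr.t and tr.t[-1] == k]
        for i in range(len(alive_now)):
            for j in range(i + 1, len(alive_now)):
                a, b = alive_now[i], alive_now[j]
                key = frozenset((a.id, b.id))
                sep = _wrap_delta(a.s[-1], b.s[-1], circ)
                prev = prev_sep.get(key)
                prev_sep[key] = sep
                if (
                    prev is not None
                    and key not in collided
                    and np.sign(sep) != np.sign(prev)
                    and 0 < abs(prev) <= 2 * max_jump_um
                    and abs(sep) <= 2 * max_jump_um
                ):
                    collided.add(key)
                    mid = (a.s[-1] - sep / 2) % (circ or np.inf)
                    events.append(dict(type="collision", s_um=mid, t_s=k * dt,
                                       collision_class="one_survives", gap_um=0.0))
        # merges: extra tracks matched to an already-taken run die here
        for ri, extras in run_extra.items():
            survivor = run_taken[ri]
            for tr in extras:
                tr.alive = False
                if k >= t_n - 2:
                    continue
                pending_merges.append(
                    dict(t=k, s=centers[ri], survivor=survivor.id, loser=tr.id)
                )
        # births
        for ri, c in enumerate(centers):
            if ri in run_taken:
                continue
            # a birth adjacent to a track that just split inherits it
            from_split = any(
                abs(_wrap_delta(c, tr.s[-1], circ)) <= 2 * max_jump_um
                for tr in active
                if tr.id in track_taken
            )
            tr = _Track(id=next_id, t=[k], s=[c], born_from_split=from_split)
            next_id += 1
            tracks.append(tr)
            recent_merge = None
            for m in pending_merges:
                if k - m["t"] <= merge_window_frames and abs(_wrap_delta(c, m["s"], circ)) <= pair_window_um:
                    recent_merge = m
                    break
            if recent_merge is not None:
                # crossing: the merged pair re-separates
                key = frozenset((recent_merge["survivor"], recent_merge["loser"]))
                if key not in collided:
                    collided.add(key)
                    events.append(
                        dict(type="collision", s_um=recent_merge["s"],
                             t_s=recent_merge["t"] * dt,
                             collision_class="one_survives", gap_um=0.0)
                    )
                pending_merges.remove(recent_merge)
                tr.born_from_split = True
            elif not from_split and k > 0:
                events.append(dict(type="initiation", s_um=c, t_s=k * dt,
                                   collision_class=np.nan, gap_um=np.nan))
            elif k == 0:
                events.append(dict(type="initiation", s_um=c, t_s=0.0,
                                   collision_class=np.nan, gap_um=np.nan))
        # deaths
        dying = [tr for tr in active if tr.id not in track_taken]
        for tr in dying:
            tr.alive = False
        dying = [tr for tr in dying if tr.t[-1] < t_n - 2]
        # pair up converging deaths -> mutual collisions
        used: set[int] = set()
        for i, a in enumerate(dying):
            if a.id in used:
                continue
            partner = None
            for b in dying[i + 1:]:
                if b.id in used:
                    continue
                sep = abs(_wrap_delta(a.s[-1], b.s[-1], circ))
                if sep > pair_window_um:
                    continue
                va, vb = a.slope(circ), b.slope(circ)
                approach = (va - vb) * _wrap_delta(a.s[-1], b.s[-1], circ) < 0
                if approach or (abs(va) < 1e-9 and abs(vb) < 1e-9):
                    partner = b
                    break
            if partner is not None:
                used.update((a.id, partner.id))
                gap = abs(_wrap_delta(a.s[-1], partner.s[-1], circ))
                mid = (a.s[-1] + _wrap_delta(partner.s[-1], a.s[-1], circ) / 2)
                events.append(dict(type="collision", s_um=mid % (circ or np.inf),
                                   t_s=a.t[-1] * dt, collision_class="mutual",
                                   gap_um=gap))
                continue
            used.add(a.id)
            # a merged pair that dies without re-separating annihilated
            # mutually at a gap below the segmentation resolution
            merged = next((m for m in pending_merges
                           if m["survivor"] == a.id
                           and a.t[-1] - m["t"] <= merge_window_frames), None)
            if merged is not None:
                pending_merges.remove(merged)
                events.append(dict(type="collision", s_um=merged["s"],
                                   t_s=a.t[-1] * dt, collision_class="mutual",
                                   gap_um=np.nan))
            else:
                events.append(dict(type="annihilation", s_um=a.s[-1],
                                   t_s=a.t[-1] * dt, collision_class=np.nan,
                                   gap_um=np.nan))

    df = pd.DataFrame(events, columns=["type", "s_um", "t_s", "collision_class",
                                       "gap_um"])
    return df.sort_values("t_s", ignore_index=True)


def terminal_gap(
    kymo: Kymograph,
    event: pd.Series | dict,
    threshold: float | str = "otsu",
    window_um: float = 30.0,
) -> float:
    """Front-to-front distance at a mutual-annihilation collision, µm.

    Reads the gray-value kymograph at the last time column (at or
    before the event) in which wave signal remains below the detection
    threshold near the event position, and measures the distance
    between the two intensity minima there (the front centrelines).
    Fronts that merged into a single trough before vanishing — overlap
    — are reported as gap 0.
    """
    v = kymo.values
    thr = float(threshold_otsu(v)) if threshold == "otsu" else float(threshold)
    ds = kymo.spacing_um
    dt = kymo.spacing_s
    n_s, n_t = v.shape
    s_evt = float(event["s_um"])
    i_evt = int(round(s_evt / ds))
    w = int(round(window_um / ds))
    offsets = np.arange(-w, w + 1)
    if kymo.periodic:
        idx = (i_evt + offsets) % n_s
    else:
        idx = np.clip(i_evt + offsets, 0, n_s - 1)
    k_evt = min(int(round(float(event["t_s"]) / dt)) + 3, n_t - 1)
    for k in range(k_evt, -1, -1):
        prof = v[idx, k]
        if prof.min() >= thr:
            continue  # fronts already vanished here; look earlier
        # local minima of the profile below threshold (plateau-aware)
        minima = []
        j = 1
        while j < len(prof) - 1:
            if prof[j] < thr and prof[j] <= prof[j - 1]:
                j2 = j
                while j2 + 1 < len(prof) and prof[j2 + 1] == prof[j]:
                    j2 += 1
                if j2 + 1 < len(prof) and prof[j2 + 1] > prof[j]:
                    minima.append((j + j2) / 2.0)
                j = j2 + 1
            else:
                j += 1
        if len(minima) >= 2:
            order = np.argsort([prof[int(round(m))] for m in minima])
            c1, c2 = sorted(np.asarray(minima)[order[:2]])
            return _two_trough_separation(prof, c1, c2) * ds
        return 0.0
    return 0.0


def _two_trough_separation(prof: np.ndarray, c1: float, c2: float) -> float:
    """Centre separation of two overlapping Gaussian troughs (pixels).

    Overlapping troughs pull each other's intensity minima inward, so
    the raw minima underestimate the front separation; a least-squares
    fit of a two-Gaussian trough model recovers the true centres.
    """
    from scipy.optimize import curve_fit

    x = np.arange(len(prof), dtype=float)
    bg = prof.max()
    depth = bg - prof.min()

    def model(x, m1, m2, a1, a2, sig):
        return bg - a1 * np.exp(-((x - m1) ** 2) / (2 * sig**2)) \
                  - a2 * np.exp(-((x - m2) ** 2) / (2 * sig**2))

    try:
        popt, _ = curve_fit(
            model, x, prof,
            p0=[c1, c2, depth, depth, max(1.0, (c2 - c1) / 3)],
            bounds=([0, 0, 0, 0, 0.5], [x[-1], x[-1], 2, 2, len(prof) / 2]),
            maxfev=5000,
        )
        return float(abs(popt[1] - popt[0]))
    except Exception:
        return float(abs(c2 - c1))


def count_rotations(
    stack: ImageStack,
    center_um: tuple[float, float],
    radius_um: float,
    max_gap_fraction: float = 0.25,
) -> int:
    """Completed revolutions of a rotating wave around a centre.

    The wavefront's angular position on a sampling circle is taken as
    the depth-weighted circular centroid around the intensity minimum
    of each frame, unwrapped over time; the count is the total swept
    angle over 2π, rounded down. Frames where the front contrast drops
    below 25% of the stack contrast are invalid; more than
    ``max_gap_fraction`` invalid frames is an error.
    """
    from .kymo import circular_kymograph

    kymo = circular_kymograph(stack, center_um, radius_um)
    v = kymo.values
    n = kymo.n_space
    depth = v.max() - v.min()
    angles = np.full(kymo.n_time, np.nan)
    for k in range(kymo.n_time):
        col = v[:, k]
        contrast = col.max() - col.min()
        if contrast < 0.25 * depth:
            continue
        i_min = int(np.argmin(col))
        w = max(2, n // 36)
        idx = (i_min + np.arange(-w, w + 1)) % n
        weights = np.clip(col.max() - col[idx], 0, None)
        offset = float(np.sum(np.arange(-w, w + 1) * weights) / np.sum(weights))
        angles[k] = 2 * np.pi * ((i_min + offset) % n) / n
    valid = np.isfinite(angles)
    if (~valid).sum() > max_gap_fraction * len(angles):
        raise ValueError("wavefront signal intermittent; rotation count unreliable")
    unwrapped = np.unwrap(angles[valid])
    total = abs(unwrapped[-1] - unwrapped[0])
    return int(np.floor(total / (2 * np.pi) + 1e-6))
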