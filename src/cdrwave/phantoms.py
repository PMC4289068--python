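"""Synthetic phantoms of circular dorsal ruffle (CDR) wave dynamics.

Purely kinematic renderings of the wave phenomenology seen in
phase-contrast time lapse: dark wavefronts (intensity troughs of ~5 µm
full width at half depth) on a bright background. Four generators cover
the observed regimes:

* :func:`make_ring_stack` — a closed ring wave whose radius follows the
  parabola R(t) = v0·t − v0/(2·t_rev)·t², i.e. it opens at speed v0,
  decelerates linearly, reverses at ``t_rev`` and closes again.
* :func:`make_annulus_stack` — a disk "cell" with a central "nucleus";
  pulse pairs fire periodically on the mid-annulus circle and propagate
  azimuthally at ±``lateral_speed``, annihilating head-on at a finite
  terminal gap or crossing.
* :func:`make_spiral_stack` — a rigidly rotating one-armed Archimedean
  spiral.
* :func:`make_kymograph_direct` — renders space–time stripe patterns
  directly (no imaging step), for unit-testing kymograph consumers.

Every generator returns the rendered data together with a
:class:`GroundTruth` record of the generating kinematics, and is
bit-reproducible for a fixed parameter set and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .containers import ImageStack, Kymograph
from .contours import Contour, ContourSeries

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "make_ring_stack",
    "make_annulus_stack",
    "make_spiral_stack",
    "make_kymograph_direct",
    "make_collision_ensemble",
]

#: FWHM = _FWHM_SIGMA * sigma for a Gaussian profile
_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PhantomParameterError(ValueError):
    """Raised when phantom parameters are inconsistent or out of bounds."""


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters for all phantom types.

    Defaults reproduce the study conditions: 5 µm front width, radial
    opening speed 0.13 µm/s, lateral pulse speed 0.12 µm/s, a 6 min
    firing period, a 12 µm terminal collision gap, and a spiral turning
    once every 525 s (eight turns in 70 min).

    Attributes
    ----------
    pixel_size, frame_interval : float
        Calibration (µm/px, s).
    shape : tuple
        (T, H, W) of the rendered stack.
    v0, t_rev : float
        Initial radial speed (µm/s) and reversal time (s) of the
        parabolic radius law R(t) = v0·t − v0/(2·t_rev)·t².
    front_width : float
        Full width at half depth of the intensity trough, µm.
    front_depth : float
        Trough contrast in [0, 1]; background is 1.
    halo_amplitude : float
        Optional bright ring just outside the trough (phase-contrast
        halo), 0 disables.
    noise_sigma : float
        Additive Gaussian noise level in intensity units.
    center : tuple or None
        Wave centre (x, y) in µm; frame centre when None.
    nucleus_radius, cell_radius : float
        Annulus geometry, µm; pulses run on the mid-annulus circle.
    lateral_speed : float
        Azimuthal pulse speed, µm/s.
    firing_period : float
        Interval between firings at each site, s.
    firing_sites : tuple of float
        Arc-length positions of firing sites on the mid circle, µm.
    terminal_gap : float
        Front-to-front distance at which colliding pulses stop and
        mutually annihilate, µm.
    collision_mode : {"annihilate", "cross"}
        Whether head-on pulses annihilate (with ``terminal_gap``) or
        pass through each other.
    rotation_period : float
        Spiral rotation period, s.
    rng_seed : int
        Seed for the noise generator.
    """

    pixel_size: float = 0.8
    frame_interval: float = 10.0
    shape: tuple[int, int, int] = (60, 96, 96)
    v0: float = 0.13
    t_rev: float = 300.0
    front_width: float = 5.0
    front_depth: float = 0.8
    halo_amplitude: float = 0.0
    noise_sigma: float = 0.0
    center: tuple[float, float] | None = None
    nucleus_radius: float = 10.0
    cell_radius: float = 25.0
    lateral_speed: float = 0.12
    firing_period: float = 360.0
    firing_sites: tuple[float, ...] = (0.0,)
    terminal_gap: float = 12.0
    collision_mode: Literal["annihilate", "cross"] = "annihilate"
    rotation_period: float = 525.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise PhantomParameterError("calibration must be positive")
        if self.front_width <= 0:
            raise PhantomParameterError("front_width must be positive")
        if not 0.0 <= self.front_depth <= 1.0:
            raise PhantomParameterError("front_depth must lie in [0, 1]")
        if self.halo_amplitude < 0 or self.noise_sigma < 0:
            raise PhantomParameterError("halo and noise amplitudes must be >= 0")
        if self.nucleus_radius >= self.cell_radius:
            raise PhantomParameterError("nucleus_radius must be < cell_radius")
        if self.terminal_gap < 0:
            raise PhantomParameterError("terminal_gap must be >= 0")

    @property
    def sigma_um(self) -> float:
        """Gaussian std of the front profile implied by the FWHM."""
        return self.front_width / _FWHM_SIGMA

    @property
    def mid_radius(self) -> float:
        """Radius of the lateral propagation path, µm."""
        return 0.5 * (self.nucleus_radius + self.cell_radius)

    def frame_center_um(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        _, h, w = self.shape
        return ((w - 1) / 2 * self.pixel_size, (h - 1) / 2 * self.pixel_size)


@dataclass
class GroundTruth:
    """Generating kinematics exported alongside every phantom.

    ``events`` has one row per wave event with columns
    (type, s_um, t_s, x_um, y_um, collision_class, gap_um); irrelevant
    columns hold NaN. The remaining fields are phantom-type specific.
    """

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    radius_um: np.ndarray | None = None
    contours: ContourSeries | None = None
    velocity_um_s: float | None = None
    period_s: float | None = None
    gap_um: float | None = None
    tip_angle_rad: np.ndarray | None = None
    rotation_count: int | None = None
    pulse_positions: list[np.ndarray] | None = None


_EVENT_COLUMNS = ["type", "s_um", "t_s", "x_um", "y_um", "collision_class", "gap_um"]


def _event_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return df


def ring_radius(params: PhantomParams, t: np.ndarray | float) -> np.ndarray:
    """Parabolic radius law R(t) = v0·t − v0/(2·t_rev)·t², clipped at 0."""
    t = np.asarray(t, dtype=float)
    r = params.v0 * t - params.v0 / (2.0 * params.t_rev) * t**2
    return np.clip(r, 0.0, None)


def _pixel_grid_um(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    _, h, w = params.shape
    y = np.arange(h) * params.pixel_size
    x = np.arange(w) * params.pixel_size
    return np.meshgrid(x, y)


def _add_noise(data: np.ndarray, params: PhantomParams) -> np.ndarray:
    if params.noise_sigma == 0:
        return data
    rng = np.random.default_rng(params.rng_seed)
    return data + rng.normal(0.0, params.noise_sigma, size=data.shape)


def make_ring_stack(params: PhantomParams) -> tuple[ImageStack, GroundTruth]:
    """Render a closed ring wave with parabolic radius evolution.

    Each frame is a bright background with a dark circular trough of
    Gaussian cross-section centred at radius R(t); optionally a bright
    halo ring sits one front-width outside the trough.

    Raises
    ------
    PhantomParameterError
        If the ring (plus its profile tails) would leave the frame.
    """
    t_frames, h, w = params.shape
    cx, cy = params.frame_center_um()
    times = np.arange(t_frames) * params.frame_interval
    radii = ring_radius(params, times)

    margin = params.front_width * 1.5 + params.halo_amplitude * params.front_width
    max_extent = radii.max() + margin
    lim = min(cx, cy, (w - 1) * params.pixel_size - cx, (h - 1) * params.pixel_size - cy)
    if max_extent > lim:
        raise PhantomParameterError(
            f"ring radius {radii.max():.1f} µm (+{margin:.1f} µm margin) "
            f"exceeds the frame half-extent {lim:.1f} µm"
        )

    xx, yy = _pixel_grid_um(params)
    rr = np.hypot(xx - cx, yy - cy)
    sigma = params.sigma_um
    data = np.empty((t_frames, h, w), dtype=float)
    for k, r0 in enumerate(radii):
        frame = 1.0 - params.front_depth * np.exp(-((rr - r0) ** 2) / (2 * sigma**2))
        if params.halo_amplitude > 0:
            frame += params.halo_amplitude * np.exp(
                -((rr - r0 - params.front_width) ** 2) / (2 * sigma**2)
            )
        data[k] = frame
    data = _add_noise(data, params)

    frames, ctimes, contours = [], [], []
    for k, r0 in enumerate(radii):
        if r0 < 1.0:  # too small to form a meaningful polygon
            continue
        n = max(16, int(round(2 * np.pi * r0 / 0.8)))
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([cx + r0 * np.cos(ang), cy + r0 * np.sin(ang)])
        frames.append(k)
        ctimes.append(times[k])
        contours.append(Contour(pts))
    series = (
        ContourSeries(frames, ctimes, contours, params.pixel_size, params.frame_interval)
        if contours
        else None
    )
    events = _event_frame(
        [
            dict(type="initiation", s_um=np.nan, t_s=0.0, x_um=cx, y_um=cy,
                 collision_class=np.nan, gap_um=np.nan),
            dict(type="annihilation", s_um=np.nan, t_s=2 * params.t_rev, x_um=cx,
                 y_um=cy, collision_class=np.nan, gap_um=np.nan),
        ]
    )
    gt = GroundTruth(events=events, radius_um=radii, contours=series,
                     velocity_um_s=params.v0)
    return ImageStack(data, params.pixel_size, params.frame_interval), gt


# ---------------------------------------------------------------------------
# 1-D pulse kinematics on a periodic circle (shared by annulus stack and
# direct kymograph rendering)
# ---------------------------------------------------------------------------

_DECAY_FRAMES = 3  # annihilating pulse pairs fade over this many frames


@dataclass
class _Pulse:
    s: float
    direction: int  # +1 / -1 along increasing arc length
    amplitude: float = 1.0
    frozen: bool = False
    decay_left: int = -1  # frames of decay remaining; -1 = not decaying


def _wrap_dist(a: float, b: float, circ: float) -> float:
    """Shortest periodic distance between arc positions a and b."""
    d = abs(a - b) % circ
    return min(d, circ - d)


def _simulate_pulses(
    params: PhantomParams,
    n_frames: int,
    single_pulse: bool = False,
    collision_pair: bool = False,
) -> tuple[list[list[tuple[float, float]]], pd.DataFrame]:
    """Advance azimuthal pulses frame by frame on the mid-annulus circle.

    Returns per-frame lists of (arc position µm, amplitude) and the
    event table. ``single_pulse`` launches one orbiting pulse (no
    collisions); ``collision_pair`` launches exactly one converging pair.
    """
    circ = 2 * np.pi * params.mid_radius
    if circ < 4 * params.front_width:
        raise PhantomParameterError(
            "lateral path circumference must be at least 4x the front width"
        )
    dt = params.frame_interval
    v = params.lateral_speed
    gap = params.terminal_gap
    annihilate = params.collision_mode == "annihilate"

    pulses: list[_Pulse] = []
    rows: list[dict] = []
    snapshots: list[list[tuple[float, float]]] = []

    if single_pulse:
        pulses.append(_Pulse(s=params.firing_sites[0] % circ, direction=+1))
        rows.append(dict(type="initiation", s_um=pulses[0].s, t_s=0.0, x_um=np.nan,
                         y_um=np.nan, collision_class=np.nan, gap_um=np.nan))
    if collision_pair:
        # symmetric pair converging on circ/2
        s1, s2 = circ * 0.25, circ * 0.75
        pulses.append(_Pulse(s=s1, direction=+1))
        pulses.append(_Pulse(s=s2, direction=-1))

    for k in range(n_frames):
        t = k * dt
        if not single_pulse and not collision_pair:
            # periodic firing: each site emits a counter-propagating pair
            if params.firing_period > 0 and t % params.firing_period < dt / 2:
                for site in params.firing_sites:
                    s0 = site % circ
                    pulses.append(_Pulse(s=s0, direction=+1))
                    pulses.append(_Pulse(s=s0, direction=-1))
                    rows.append(dict(type="initiation", s_um=s0, t_s=t, x_um=np.nan,
                                     y_um=np.nan, collision_class=np.nan,
                                     gap_um=np.nan))

        # detect head-on pairs reaching the terminal gap
        active = [p for p in pulses if not p.frozen and p.decay_left < 0]
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                if a.direction == b.direction:
                    continue
                d_now = _wrap_dist(a.s, b.s, circ)
                # positions after one more step
                d_next = _wrap_dist(
                    (a.s + a.direction * v * dt) % circ,
                    (b.s + b.direction * v * dt) % circ,
                    circ,
                )
                closing = d_next < d_now
                if not closing:
                    continue
                if annihilate and d_now <= gap + 2 * v * dt:
                    # freeze symmetrically at exactly the terminal gap
                    excess = (d_now - gap) / 2.0
                    a.s = (a.s + a.direction * excess) % circ
                    b.s = (b.s + b.direction * excess) % circ
                    a.frozen = b.frozen = True
                    a.decay_left = b.decay_left = _DECAY_FRAMES
                    mid = (a.s + _wrap_dist(a.s, b.s, circ) / 2 * a.direction) % circ
                    rows.append(dict(type="collision", s_um=mid, t_s=t, x_um=np.nan,
                                     y_um=np.nan, collision_class="mutual",
                                     gap_um=gap))
                elif not annihilate and d_next <= v * dt:
                    rows.append(dict(type="collision",
                                     s_um=(a.s + d_now / 2 * a.direction) % circ,
                                     t_s=t, x_um=np.nan, y_um=np.nan,
                                     collision_class="one_survives", gap_um=0.0))

        snapshots.append([(p.s, p.amplitude) for p in pulses if p.amplitude > 0])

        # advance to next frame
        for p in pulses:
            if p.decay_left >= 0:
                p.decay_left -= 1
                p.amplitude = max(0.0, p.decay_left / _DECAY_FRAMES)
            elif not p.frozen:
                p.s = (p.s + p.direction * v * dt) % circ
        pulses = [p for p in pulses if p.amplitude > 0]

    return snapshots, _event_frame(rows)


def make_annulus_stack(
    params: PhantomParams, single_pulse: bool = False
) -> tuple[ImageStack, GroundTruth]:
    """Render azimuthally propagating pulses on a disk cell with nucleus.

    Pulse pairs fire at ``firing_sites`` every ``firing_period`` seconds
    and run along the mid-annulus circle at ±``lateral_speed``. Head-on
    pairs either stop at ``terminal_gap`` and fade (annihilate mode) or
    pass through (cross mode). With ``single_pulse`` one pulse orbits
    indefinitely (the disk-cell orbiting regime).
    """
    t_frames, h, w = params.shape
    cx, cy = params.frame_center_um()
    snapshots, events = _simulate_pulses(params, t_frames, single_pulse=single_pulse)

    xx, yy = _pixel_grid_um(params)
    rr = np.hypot(xx - cx, yy - cy)
    phi = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    r_mid = params.mid_radius
    circ = 2 * np.pi * r_mid
    s_px = phi * r_mid
    sigma_s = params.sigma_um
    sigma_r = (params.cell_radius - params.nucleus_radius) / 4.0
    radial_env = np.exp(-((rr - r_mid) ** 2) / (2 * sigma_r**2))
    nucleus = 0.45 * (1.0 - _smoothstep(rr, params.nucleus_radius - 1.0,
                                        params.nucleus_radius + 1.0))

    data = np.empty((t_frames, h, w), dtype=float)
    pulse_positions: list[np.ndarray] = []
    for k, snap in enumerate(snapshots):
        frame = 1.0 - nucleus
        for s_p, amp in snap:
            d = np.abs(s_px - s_p)
            d = np.minimum(d, circ - d)
            frame = frame - params.front_depth * amp * radial_env * np.exp(
                -(d**2) / (2 * sigma_s**2)
            )
        data[k] = frame
        pulse_positions.append(np.array([s for s, _ in snap]))
    data = _add_noise(data, params)

    gt = GroundTruth(events=events, velocity_um_s=params.lateral_speed,
                     period_s=params.firing_period,
                     gap_um=params.terminal_gap if params.collision_mode == "annihilate" else 0.0,
                     pulse_positions=pulse_positions)
    return ImageStack(data, params.pixel_size, params.frame_interval), gt


def _smoothstep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3 - 2 * t)


def make_spiral_stack(params: PhantomParams) -> tuple[ImageStack, GroundTruth]:
    """Render a rigidly rotating one-armed Archimedean spiral wave.

    The arm follows r = b·θ with pitch chosen so the arm spans the cell
    disk in 1.5 turns; the whole pattern rotates once per
    ``rotation_period``. Ground truth stores the unwrapped tip angle and
    the completed rotation count over the stack duration.
    """
    t_frames, h, w = params.shape
    cx, cy = params.frame_center_um()
    omega = 2 * np.pi / params.rotation_period
    b = params.cell_radius / (3 * np.pi)  # 1.5 turns to the rim

    xx, yy = _pixel_grid_um(params)
    rr = np.hypot(xx - cx, yy - cy)
    phi = np.arctan2(yy - cy, xx - cx)
    sigma = params.sigma_um
    k_max = int(np.ceil(params.cell_radius / (2 * np.pi * b))) + 1
    rim = 1.0 - _smoothstep(rr, params.cell_radius - 1.0, params.cell_radius + 1.0)

    times = np.arange(t_frames) * params.frame_interval
    data = np.empty((t_frames, h, w), dtype=float)
    for k, t in enumerate(times):
        theta = (phi - omega * t) % (2 * np.pi)
        dist = np.full_like(rr, np.inf)
        for m in range(k_max + 1):
            arm_r = b * (theta + 2 * np.pi * m)
            dist = np.minimum(dist, np.abs(rr - arm_r))
        frame = 1.0 - params.front_depth * rim * np.exp(-(dist**2) / (2 * sigma**2))
        data[k] = frame
    data = _add_noise(data, params)

    tip_angle = omega * times  # rigid rotation, tip pinned to the rim
    duration = times[-1] if t_frames > 1 else 0.0
    count = int(np.floor(duration / params.rotation_period + 1e-9))
    gt = GroundTruth(events=_event_frame([]), tip_angle_rad=tip_angle,
                     rotation_count=count, period_s=params.rotation_period)
    return ImageStack(data, params.pixel_size, params.frame_interval), gt


def make_kymograph_direct(
    params: PhantomParams,
    mode: Literal["pulses", "stripes", "collision"] = "stripes",
) -> tuple[Kymograph, GroundTruth]:
    """Render a periodic space–time stripe pattern without the imaging step.

    Modes
    -----
    pulses
        One pulse orbiting forever: a single wrapped stripe of slope
        ``lateral_speed``.
    stripes
        Periodic firing at ``firing_sites``; each firing spawns a
        counter-propagating pair that annihilates (or crosses) head-on.
    collision
        Exactly one converging pair terminating with ``terminal_gap``
        (annihilate mode) or passing through (cross mode).
    """
    n_frames = params.shape[0]
    circ = 2 * np.pi * params.mid_radius
    n_space = int(round(circ / params.pixel_size))
    snapshots, events = _simulate_pulses(
        params,
        n_frames,
        single_pulse=(mode == "pulses"),
        collision_pair=(mode == "collision"),
    )
    s_axis = np.arange(n_space) * params.pixel_size
    sigma_s = params.sigma_um
    values = np.ones((n_space, n_frames), dtype=float)
    last_positions: list[np.ndarray] = []
    for k, snap in enumerate(snapshots):
        for s_p, amp in snap:
            d = np.abs(s_axis - s_p)
            d = np.minimum(d, circ - d)
            values[:, k] -= params.front_depth * amp * np.exp(-(d**2) / (2 * sigma_s**2))
        last_positions.append(np.array([s for s, _ in snap]))
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.rng_seed)
        values = values + rng.normal(0.0, params.noise_sigma, size=values.shape)

    gap = params.terminal_gap if params.collision_mode == "annihilate" else 0.0
    gt = GroundTruth(events=events, velocity_um_s=params.lateral_speed,
                     period_s=params.firing_period, gap_um=gap,
                     pulse_positions=last_positions)
    kymo = Kymograph(values, spacing_um=params.pixel_size,
                     spacing_s=params.frame_interval, periodic=True)
    return kymo, gt


def make_collision_ensemble(
    n: int,
    fraction_annihilate: float,
    seed: int,
    params: PhantomParams | None = None,
) -> tuple[list[Kymograph], list[str]]:
    """Generate a labelled ensemble of collision kymographs.

    Exactly ``round(n * fraction_annihilate)`` members are rendered in
    annihilate mode and the rest in cross mode, in an order shuffled by
    ``seed``. Pulse speeds are jittered ±15% between members so the
    ensemble is not a single repeated image.
    """
    if n <= 0:
        raise ValueError("ensemble size must be positive")
    if not 0.0 <= fraction_annihilate <= 1.0:
        raise ValueError("fraction_annihilate must lie in [0, 1]")
    base = params or PhantomParams(shape=(80, 1, 1))
    n_annihilate = int(round(n * fraction_annihilate))
    labels = ["annihilate"] * n_annihilate + ["cross"] * (n - n_annihilate)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    kymos: list[Kymograph] = []
    for i, label in enumerate(labels):
        speed = base.lateral_speed * float(rng.uniform(0.85, 1.15))
        p = replace(base, collision_mode=label, lateral_speed=speed,
                    rng_seed=int(rng.integers(0, 2**31 - 1)))
        kymo, _ = make_kymograph_direct(p, mode="collision")
        kymos.append(kymo)
    return kymos, labels
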