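# cdrwave

Quantitative wavefront dynamics of **circular dorsal ruffles (CDRs)** —
ring-shaped actin waves that travel across the dorsal surface of adherent
cells and appear as dark, ~5 µm wide fronts in phase-contrast time lapse.
`cdrwave` provides the full measurement chain a lab would run on such
movies, plus a synthetic phantom generator so every stage is testable
without microscope data:

- **Contour tracking** — gradient-vector-flow (GVF) active contours lock a
  closed snake onto the intensity trough of each frame; a cubic-polynomial
  relaxation along local normals removes the snake's bending-energy bias,
  followed by 0.8 µm arc-length resampling and coordinate smoothing.
- **Kinematics** — per-vertex normal velocity by ray–contour intersection,
  signed curvature from circumscribed circles, enclosed area, and the
  collapse of mean velocity v̄ against normalized area a = A/A_max. For a
  wave whose radius follows the parabola R(t) = v₀·t − v₀/(2·t_rev)·t², the
  collapse obeys a(v) = (1 − (v/v₀)²)², i.e. v(a) = v₀·√(1 − √a); fitting
  this form and evaluating it at a = 0 extrapolates the initial front
  speed v₀.
- **Kymographs** — intensity sampled along lines through wave origins or
  circles around the nucleus of disk-shaped cells (periodic arc-length
  axis), ROI minimum-intensity traces, recovery times τ, and per-event
  maximal radial extension R_max with box-binned statistics.
- **Spatiotemporal statistics** — Otsu segmentation, the normalized
  autocorrelation c(Δs, Δt) (circular in space, unbiased in time),
  propagation velocities from the dominant ridge orientation of the
  Radon-transformed map, inter-event periods from the c(0, Δt) cut, and
  detection/classification of wave events: initiations ("<" shapes),
  mutual annihilations with a finite terminal gap, crossings, and spiral
  rotation counts.
- **Phantoms** — kinematic renderings (no reaction–diffusion dynamics) of
  parabolic ring waves, azimuthally firing pulse pairs on an annulus,
  rigidly rotating spirals, and direct space–time stripe patterns, each
  with exported ground truth and bit-reproducible for a fixed seed.

## Worked example

Track a noiseless parabolic ring phantom generated at v₀ = 0.13 µm/s and
extrapolate the velocity–area collapse back to zero area:

```python
import numpy as np
from cdrwave import (PhantomParams, SnakeConfig, Contour,
                     make_ring_stack, make_kymograph_direct)
from cdrwave.snakes import track_sequence
from cdrwave.kinematics import (series_kinematics, velocity_area_collapse,
                                fit_extrapolate_v0)
from cdrwave.stats import (segment_kymograph, autocorrelation_2d,
                           radon_velocity, cuts, period_from_cut)

params = PhantomParams(v0=0.13, t_rev=300.0, shape=(51, 96, 96),
                       frame_interval=6.0)
stack, truth = make_ring_stack(params)
cx, cy = params.frame_center_um()
k0 = int(np.argmax(truth.radius_um >= 4.0))
ang = np.linspace(0, 2 * np.pi, 60, endpoint=False)
r_seed = truth.radius_um[k0] + 2
seed = Contour(np.column_stack([cx + r_seed * np.cos(ang),
                                cy + r_seed * np.sin(ang)]))
series = track_sequence(stack, seed, SnakeConfig(),
                        frame_range=(k0, stack.n_frames))
records = series_kinematics(series)
fit = fit_extrapolate_v0(velocity_area_collapse([records], bin_width=0.05))
print(f"tracked {len(series)} frames, extrapolated v(a=0) = {fit.v0:.4f} um/s")

kymo, _ = make_kymograph_direct(
    PhantomParams(shape=(240, 1, 1), lateral_speed=0.12,
                  firing_period=360.0, frame_interval=20.0), mode="stripes")
cmap = autocorrelation_2d(segment_kymograph(kymo))
(lags_s, c0), _ = cuts(cmap)
print(f"lateral speed {radon_velocity(cmap).speed:.3f} um/s, "
      f"period {period_from_cut(lags_s, c0)/60:.2f} min")
```

prints

```
tracked 45 frames, extrapolated v(a=0) = 0.1278 um/s
lateral speed 0.122 um/s, period 6.00 min
```

The first line says the tracker followed the opening ring through 45
frames and that the collapse fit recovered the generating initial speed to
within 0.002 µm/s. The second line is the disk-cell analysis: pulses
rendered at 0.12 µm/s with a 6 min firing period are recovered from the
autocorrelation map's ridge orientation and its zero-space-lag cut.

A command-line interface mirrors the library (`cdrwave simulate`, `track`,
`kinematics`, `kymo`, `stats`, `binarize`); every run writes its resolved
parameters next to its outputs.

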