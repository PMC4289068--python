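# Methods

`cdrwave` measures the kinematics and spatiotemporal statistics of
circular dorsal ruffles (CDRs) — closed actin wavefronts on the dorsal
cell surface that image as dark troughs (~5 µm full width at half depth)
on a bright phase-contrast background. This note records the models,
estimators, parameter choices and numerical conventions, and what the
synthetic phantoms do and do not establish about real data.

## Coordinate and intensity conventions

Pixel centres sit at integer indices, origin top-left, x rightward
(columns), y downward (rows). All exported geometry is in µm and
seconds; frame indices are 0-based. Wavefronts are intensity *minima*
(maximal actin density maps to minimal phase-contrast intensity);
phantom backgrounds are normalized to 1 with trough contrast
`front_depth` ∈ [0, 1]. Contours are stored counter-clockwise in the
stored x/y algebra (positive shoelace area), which fixes the outward
normal as the tangent rotated by −90° and hence the sign convention:
positive normal velocity = outward growth.

## Contour tracking

Each frame is tracked with a classic active contour under gradient
vector flow (GVF). The edge map is the negated, range-normalized
intensity, optionally pre-blurred by 1 px; the GVF field (u, v) solves
µ∇²u = (u − f_x)|∇f|² by explicit diffusion with step
dt = 1/(4µ + max|∇f|²), run to a 1e-8 fixed-point tolerance or an
iteration cap (default 500). Internal elasticity α and rigidity β act
semi-implicitly through a circulant system solve; the external GVF
force is evaluated at the current vertices by bilinear interpolation.
Defaults (α = 0.05, β = 0.02, step 1.0, external weight 2.0, µ = 0.2)
were validated on noiseless ring phantoms, where the full pipeline
tracks the generating radius to well under half a pixel; none of them
is critical within a factor of a few. Convergence is declared when the
maximal per-vertex displacement drops below 0.05 µm (cap 200
iterations).

Because the snake's bending energy biases vertices away from high
curvature, a final relaxation decouples the measurement from the
regularization: the intensity along each vertex's outward normal is
sampled bilinearly over ±2 µm (≈0.25 px steps), fitted with a cubic
polynomial, and the vertex moved to the cubic's interior global
minimum; vertices whose cubic has no interior minimum, whose profile is
flat, or whose profile would leave the frame stay put. The contour is
then resampled to equal 0.8 µm arc-length spacing (the resolution limit
of a 10x objective; point count = round(perimeter/spacing), first
vertex preserved) and the coordinate sequences are smoothed with a
circular Gaussian of σ = 0.8 µm. A Gaussian was chosen for the final
smoothing because a derivative kernel cannot smooth; at this width it
shrinks a 10 µm circle by <1% while attenuating single-vertex spikes by
more than half. Tracking seeds each frame with the previous frame's
converged contour; on loss (collapse, degenerate polygon, too-short
perimeter) the series built so far is returned with a warning naming
the failing frame.

## Kinematics and the velocity–area collapse

Per-vertex normal velocity casts a bidirectional ray along the outward
normal from the contour at t and intersects it with the linearly
interpolated contour at t+Δt; the nearest intersection within a 5 µm
cutoff wins, with ties broken toward the outward side, and misses are
NaN. Curvature is the inverse circumradius (Menger curvature) of each
vertex and its ±2.4 µm arc-length neighbours, signed positive where the
contour is locally convex. Area is the shoelace formula, with
self-intersecting polygons rejected (degenerate collinear ones return
0). A divergence-theorem identity, dA/dt ≈ perimeter × v̄ evaluated with
the midpoint perimeter, holds within 10% on tracked series and serves
as an internal consistency test.

A wave whose radius follows R(t) = v₀·t − v₀/(2·t_rev)·t² (the minimal
parabola with R(0) = 0, symmetric about the reversal time t_rev) has
mean velocity v(t) = v₀(1 − t/t_rev) and normalized area
a = (R/R_max)², which eliminate t to give the closed-form collapse
a(v) = (1 − (v/v₀)²)², i.e. v(a) = v₀√(1 − √a) — the unique quartic
consistent with parabolic radius evolution. The collapse pools
opening-phase points (frames before each wave's maximal area; A_max is
taken per wave over its tracked lifetime), bins them in a with
width-0.05 box medians, and fits the closed form by least squares over
populated bins (≥5 required). A free fourth-order polynomial is
available as a fallback (`method="quartic"`). Fits whose RMS residual
exceeds 15% of the fitted v₀ are flagged non-parabolic; this threshold
cleanly separates parabolic phantoms (residuals ≲1% of v₀) from
constant-velocity controls.

The curvature–velocity analysis reports the Pearson correlation of all
pooled per-vertex (κ, v) pairs (≥100 required, zero variance is an
error) plus the mean per-contour circular cross-correlation versus
arc-length lag, so a spatially shifted coupling would still register.
On curvature-uniform phantoms (expanding, translating circles) |r|
stays below 0.1; on contours moved by an eikonal rule v = v₀ − Dκ it
reaches −0.9 and beyond.

## Kymographs, recovery times, R_max

Linear kymographs sample each frame bilinearly along a line at one
pixel per step; circular kymographs sample a circle at one pixel of arc
(round(2πr/pixel) points), making the space axis periodic with period
2πr. ROI minimum-intensity traces smooth the ROI with a σ = 2 µm
Gaussian before taking the minimum. Events in a trace are maximal runs
below a threshold (default: midpoint of trace median and minimum, the
median being the CDR-free baseline); the recovery time τ counts the
above-threshold frames between consecutive events, so two events
separated by a single bright frame give τ of one frame interval, and a
literal zero-gap pair is a single run and yields no τ. R_max per event
is measured on a linear kymograph through the wave origin: each
connected dark component is one event, and within it the maximal
half-distance between the two branch centrelines (centrelines, not the
envelope edges, which would inflate the estimate by the front
half-width). (R_max, τ) pairs are box-binned in R_max with 10 µm width,
reporting median, quartiles and counts per bin.

## Autocorrelation, Radon velocities, periods

The autocorrelation c(Δs, Δt) of a (by default binarized) kymograph is
mean-subtracted and variance-normalized, computed by FFT — circular
along the periodic space axis, zero-padded along time with unbiased
normalization (each time lag divided by its overlap count) — so
c(0,0) = 1 exactly and c(Δs, Δt) = c(−Δs, −Δt). An FFT-vs-direct-sum
oracle test pins the implementation to 1e-10 on small inputs. Maps from
different cells are averaged element-wise, with linear resampling onto
a common lag grid when grids differ.

Velocities come from the ridge orientation of the map: the map is
cropped square about zero lag, the central 3×3 bins (the
uninformative c(0,0) spike) blanked, a circular window applied, and the
Radon transform taken over a 0.5° angle grid. Integrating parallel to a
ridge maximizes the projection variance; a stripe of slope m (Δs px per
Δt px) peaks at θ = 90° − atan(m), so v = cot(θ) · (Δs spacing)/(Δt
spacing), with peak angles refined by parabolic interpolation. Both
signs appear for bidirectional propagation, and the per-cell statistic
is the mean |v| over dominant orientations. A peak counts as dominant
only when its variance exceeds 10× the median variance over all
angles: oriented maps exceed this margin by two orders of magnitude
(measured 220–930×) while isotropic noise maps stay below 5×. A
permutation null (shuffling map rows/columns) was evaluated and
rejected: shuffles destroy the intrinsic smoothness of a correlation
map, so even isotropic maps test as "significant", and purely static
patterns (horizontal ridges) are invariant under row shuffles, making
v = 0 undetectable. The ratio criterion is also deterministic.

The inter-event period is read from the c(0, Δt) cut: after light
[0.25, 0.5, 0.25] smoothing, the first negative excursion (the
quiescent interval) is located, and the period is the intensity-
weighted centroid of the following positive lobe — robust to bin-scale
noise on a symmetric peak, and exact on noiseless phantoms. Cuts
without a negative excursion return no period.

## Event detection and classification

Segmented kymographs are analyzed by linking per-column dark runs into
tracks with greedy nearest-neighbour association against a
constant-velocity prediction (wrap-aware on periodic axes, max jump
6 µm/frame by default). Events:

- **initiation** — a track born away from existing tracks (the apex of
  a "<"; the immediate split into counter-propagating branches belongs
  to the same event);
- **collision, mutual** — two converging tracks dying together
  (within 2 frames and 25 µm), with the gap between their final
  centres recorded; or a merged pair that dies without re-separating
  (fronts closer than the segmentation can resolve);
- **collision, one_survives** — converging tracks that cross, detected
  either by a separation sign flip at close approach or by a merge
  followed by a re-split within 12 frames;
- **annihilation** — an unpaired death.

Deaths in the last two columns are attributed to the end of the
recording. Track linking was chosen over skeleton branch-point
labelling because junction geometry in thick (~5 µm) segmented stripes
is unreliable at the 2-bin localization the events need; on noiseless
ensembles the classifier recovers generated labels perfectly (verified
on 100-member ensembles across several seeds).

The terminal gap of a mutual annihilation is measured on the
*gray-value* kymograph at the last time column where wave signal
remains below the detection threshold near the event: the front
positions are the centres of a two-Gaussian trough model fitted by
least squares. Overlapping troughs pull each other's raw intensity
minima inward (a rendered 5 µm separation reads ~3.9 µm from raw
minima), and the mixture fit removes exactly this bias; fronts that
merged into a single trough report gap 0.

Spiral rotations are counted on a circular kymograph around the given
centre: per frame, the front angle is the depth-weighted circular
centroid around the intensity minimum; angles are unwrapped over time
and the count is the total swept angle over 2π, rounded down (with a
1e-6 guard against floating-point shortfall at exact multiples).
Frames with front contrast below 25% of the stack contrast are invalid;
more than 25% invalid frames is an error.

## Synthetic phantoms

The generators are purely kinematic renderings — no reaction–diffusion
or mechanochemical dynamics — of the observed wave regimes, with
Gaussian trough cross-sections whose full width at half depth is
`front_width`. Defaults are the study conditions: pixel size 0.8 µm
(10x objective resolution), front width 5 µm, depth 0.8, radial opening
speed v₀ = 0.13 µm/s, lateral pulse speed 0.12 µm/s, orbit speed for
the single-pulse regime 0.21 µm/s, firing period 360 s, terminal
collision gap 12 µm, spiral rotation period 525 s (eight turns in
70 min), nucleus/cell radii 10/25 µm. Noise, when enabled, is additive
Gaussian (`noise_sigma`, a free parameter — the phase-contrast noise of
the original movies is not quantified anywhere we could anchor it; the
mild default used in tests, σ = 0.05 of the background, makes the
segmentation non-trivial without burying the 0.8 contrast). The
phase-contrast halo is rendered, when enabled, as a Gaussian bright
ring offset one front width outward; it defaults to off so width
measurements are not confounded. Annihilating pulse pairs freeze at
exactly the terminal gap (with sub-step position correction) and fade
linearly over 3 frames; the decay profile is a rendering choice, not a
measurement. Identical parameters and seed give bit-identical output.

Phantom problem sizes used throughout the tests and the acceptance
script — 96×96 px frames, 45–240 frame sequences, 10-map ensembles for
the velocity average and 100-member ensembles for collision
classification — were chosen so each stage is exercised end to end at
the study's physical scales with comfortable margins on a single CPU.

**What passing phantoms does and does not show.** The phantoms have
Gaussian cross-sections, rigid kinematics, stationary backgrounds, and
(at most) white noise. Passing them demonstrates that the estimators
are unbiased and internally consistent under the stated wave geometry
and calibration — not that they are robust to out-of-focus drift,
uneven illumination, wavefront instabilities, neighbouring cells, or
organelle clutter, all of which real movies contain. The contour
tracker in particular inherits the classic snake's need for a
reasonable initialization (a user-drawn seed polygon), and event
detection assumes fronts separated by at least about four front widths,
as in the micro-patterned disk-cell geometry.

## Known limitations

- One contour per tracked wave: splitting or merging wavefronts end a
  track rather than forking it.
- The velocity–area extrapolation presumes the parabolic radius law;
  the non-parabolic flag reports when that presumption fails, but no
  alternative growth law is fitted.
- Radon velocities assume straight ridges (constant speed) within the
  analyzed lag window; accelerating pulses blur the variance peak.
- R_max from kymographs requires the sampling line to pass through the
  wave origin; off-centre lines underestimate.
- The event classifier's windows (6 µm/frame jump, 12-frame merge
  window, 25 µm pairing) suit speeds and widths near the defaults;
  far outside that regime they should be re-examined.
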