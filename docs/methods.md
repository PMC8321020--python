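# Methods

This note records the model behind each pipeline stage, the parameters
that matter, and the choices made where the design was genuinely open.

## Imaging model and coordinate conventions

Frames are `(rows, cols, channels)` 8-bit images; the red channel carries a
nuclear label and the green channel a microtubule label (a third channel
may exist and is ignored). Default acquisition metadata: 10 s per frame,
0.21 μm per pixel, 512 × 672 frames. Positions are `(x, y)` with
x = column, y = row, 0-based, pixel centres at integer coordinates. All
angles are counter-clockwise positive *with the image viewed y-up* (row
axis negated); this one convention is used by the generator, the
direction-change measurement and the alignment, so planted and measured
angles are directly comparable. Frames are 0-based everywhere except the
human-facing `summary.txt`, which is 1-based; every CSV states the
convention in a leading `#` comment.

## Segmentation

Foreground is defined as intensity ≥ level. The Otsu level maximizes the
between-class variance of the 256-bin histogram with background = bins
below the level; ties are broken at the lowest maximizing level, and a
single-valued histogram is flagged degenerate (the frame is treated as
empty rather than all-foreground). Hysteresis keeps connected components
of the low mask (≥ low) that contain at least one high pixel (≥ high),
8-connected by default.

How two hysteresis levels should derive from the one Otsu criterion is an
open design point; two modes are provided:

- `two_class` (default): high = Otsu level, low = α·high with α = 0.5.
- `three_class`: low and high are the two thresholds of a three-class
  (multi-)Otsu split, shifted by one intensity level to match the
  ≥-convention of this module.

Components smaller than `min_area` = 20 px are discarded (the nucleus disk
at the default radius covers ~80 px). Nucleus centroids are plain pixel
means of the red regions. Post-processing beyond the minimum-area filter
(morphological smoothing, hole filling) is deliberately absent.

## Tracking

The keyhole gate reproduces the intent of keyhole-style phagocyte
trackers: a detection continues a track if it lies within a fallback
circle around the last position (default radius: 3 × the median
frame-to-frame nearest-neighbour displacement, so ~3 × cell speed) or
inside a wedge of half-angle 30° opened along the last displacement with
length 3 × that displacement. Conflicts are resolved greedily by distance
to the linearly predicted position; equidistant candidates go to the
lowest detection index, making the result deterministic given input
order. A track may miss one frame (bridged by linear interpolation,
flagged as such); two consecutive misses terminate it, and a reappearing
cell starts a new track — speculative gap closing would corrupt contact
timing. A plain nearest-neighbour circular gate is available as
`mode="nearest"`.

## Clumps and interactions

Clump membership uses the nucleus centroid inside the green region. This
is robust to partial halo overlap (nuclei stay separate when halos merge);
an area-overlap mode exists for data where centroids are unreliable.
Membership runs are not smoothed by default; `bridge_gap=1` merges runs of
identical membership separated by a single missing frame.

Time in clump is the difference T_C = t_kC − t_k0, and seconds are
T_C × frame interval. Note the inclusive frame count of a run is
T_C + 1 and is reported separately as `n_frames` in the clump table; the
two conventions differ by one frame and are easy to conflate.

Direction vectors are endpoint displacements over the S-frame windows, not
line fits — the measurement is defined by the positions at the window
boundaries. The aligned frame drops the within-clump displacement by
design (within-clump movement is not analysed): the post window is
re-anchored at the contact exit point and rotated by the same angle as the
pre window, so post paths emanate from the origin and the aligned post
direction equals θ_x. A cell whose window displacement is exactly zero has
no defined angle; it is kept in the interaction row, flagged, and excluded
from angle statistics. Exit distance defaults to the endpoint distance
from the origin; a cumulative path-length mode is provided because "length
of the track after leaving" is also a reasonable reading. When a pair
re-contacts, each instance yields an independent interaction row, and each
qualifying cell contributes one angle (so one interaction can contribute
two angles). The selection window is required in full (exactly S frames on
both sides); S defaults to 5 with 3–5 as the sweep range of interest.

## Group statistics

Per-dataset counts use the sample (n − 1) standard deviation; datasets
with zero suitable interactions are excluded from count summaries (they
contribute no measurements), and a single-dataset group reports its SD as
unavailable. The t-test is Student's pooled-variance by default — the
common default of the numerical environment the original analysis ran in —
with Welch available by flag. The |θ_x| < 90° filter is strict (±90°
exactly is excluded). No multiple-testing correction is applied; the
comparison report states how many tests were run.

## Synthetic data generator

The generator emulates the study conditions: two-channel movies of
nucleus + halo cells (defaults: nucleus radius 5 px, halo radius 12 px,
speed 4 px/frame, 512 × 672 frames) with programmed pairwise contacts.
Cells move with piecewise-constant velocity; during a contact the pair
pivots about a fixed midpoint at separation 2·halo_radius − 3 px, so halos
overlap while nuclei stay > 2·nucleus_radius + 2 px apart. The relative
entry (exit) vector is placed anti-parallel (parallel) to the relative
pre- (post-) velocity, which makes the centre distance grow monotonically
outside the programmed interval — halo overlap starts and ends
frame-exactly, giving exact T_C ground truth. Choosing the relative entry
heading as π − D/2 (D = wrapped turn-angle difference) bounds the
separation rate below by 2·speed·cos(D/4) ≥ 1.41·speed for any turn pair.

Validation is strict rather than forgiving: scenarios are rejected (with a
reason) when events overlap for a cell, the speed is too low for
frame-exact boundaries, halo_radius < nucleus_radius + 3, trajectories
would leave the frame (no silent clamping), unprogrammed pairs come within
halo range, or a choreographed step exceeds 3 × speed (which would break
the tracking gate). Single-frame contacts generally fail the exit-geometry
check and are rejected. Rendering draws hard-edged disks (foreground 200,
background 0) with optional Gaussian blur and additive Gaussian noise; the
zero background keeps the low hysteresis level above background even for
noise-free two-valued frames.

What the generator does not model — and therefore what passing recovery
tests do not show about real data: deformable cell shapes and microtubule
arm-like protrusions, intensity/focus drift, uneven illumination,
cell division and entry/exit through the field of view, and more than two
cells meeting in one programmed event (three-cell clumps can still be
built by hand-written trajectories, as the tests do).

## Numerical choices and problem sizes

Exact reversals map to +π so θ_x ∈ (−π, π] is closed on the positive side.
Alignment is a pure rotation + translation (distances preserved to
~1e-13). The Otsu implementation is vectorised cumulative moments and is
checked against an exhaustive-search oracle. Test and acceptance runs use
60-frame 360 × 440 movies, 100-replicate invariant sweeps and a
1000-replicate t-test null calibration; these sizes make the checks sharp
(recovery errors come out ~50× below the 15° acceptance bound) while the
whole suite runs in seconds.

## Known limitations

- The keyhole parameter defaults are this package's own calibration, not
  values from the original phagocyte tracker, which are unpublished.
- Membership-by-centroid can mislabel when segmentation fragments a halo.
- The headline biological comparison (control vs mutant macrophages,
  p = 0.03 on |θ_x| < 90°) requires the original movies; this package
  demonstrates the machinery on synthetic ground truth and reproduces the
  study's printed summary statistics from its printed counts.
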