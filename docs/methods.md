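# Methods

## Scope and model of the data

`tirfpuncta` quantifies diffraction-limited fluorescent puncta — vesicles
such as CD63-labelled multivesicular bodies (MVBs) or NPY-labelled insulin
secretory granules (ISGs) — in single-cell TIRF time-lapse movies. A movie
is a calibrated `(T, Y, X)` intensity array with a pixel size (µm/pixel) and
frame interval (s/frame) supplied by the user; calibration is never read
from file metadata. All downstream quantities (densities per µm², residence
times in seconds, band widths in µm) derive from these two numbers.

The analysis chain is: cell-footprint segmentation → per-frame spot
detection → ΔF fluorometry at candidate ROIs → track linking → fusion
detection and release-duration measurement → residence-behaviour
classification → peripheral/non-peripheral zoning → group statistics.

## Spot detection

A punctum is a local intensity maximum whose height above the saddle
connecting it to any brighter region exceeds a prominence threshold (the
"noise tolerance" notion of ImageJ-style find-maxima). We compute this with
the morphological h-maxima transform: greyscale reconstruction of
`image − h` under `image` leaves a dome of height `h` exactly at regional
maxima of dynamics ≥ `h`, so the saddle criterion is evaluated exactly
rather than by a window approximation. Plateau maxima reduce to their
top-left pixel; detections closer than a minimum separation (default 3 px)
merge keeping the brighter.

The default prominence is 5 × a robust noise estimate. Noise is estimated
from first differences — horizontally within a frame for single images, or
between the first two frames for movies — because a plain MAD over the
frame treats the cell-baseline step as noise and roughly doubles the
threshold in realistic scenes. Puncta density is the in-mask detection
count on one designated frame (default: the first) divided by the mask
area; the mean spot intensity is the mean of in-mask peak intensities.

Detection bias stays below 10% up to ~1.1 puncta/µm² at 0.16 µm/px and
SNR ≥ 10; beyond that, neighbouring puncta closer than ~4.3 px share a
saddle higher than `peak − prominence` and merge. This is a resolvability
limit of the data, not a tunable.

## ΔF fluorometry

For an ROI centred on an integer pixel, ΔF per frame is the mean over a
central circle (default diameter 3 px → 9 pixels, corners included since
√2 < 1.5) minus the mean over the surrounding annulus (outer diameter 5 px
→ 12 pixels). Pixel membership is decided by whether the pixel centre lies
within diameter/2 of the ROI centre; a plus-shaped (5-pixel) inner circle is
selectable because the original 3-pixel circle convention cannot be
recovered unambiguously. ΔF is exactly invariant to additive offsets, and
under i.i.d. Gaussian pixel noise its sd is `σ √(1/n_c + 1/n_a)`
(≈ 0.441 σ for the 9/12 geometry) — both are used as self-tests. Diameters
are pixel counts, not µm: the 3/5 defaults correspond to 0.16 µm/px and are
kept as pixel counts at other calibrations unless overridden.

## Fusion detection and release duration

A fusion (exocytosis) event is an abrupt, permanent loss of a punctum's
fluorescence. Candidates are linked tracks that (i) end before the movie's
final frames, (ii) were present and confined (within 0.3 µm of their median
position) for at least the stable-docking requirement — by default the
40-frame residence threshold — and (iii) whose ΔF trace yields a complete
release measurement. Once measured, no punctum may be re-detected within
the confinement radius of the site for the rest of the movie; reappearance
vetoes the event. Events whose decay has not finished before the movie ends
are excluded rather than truncated.

The stable-docking precondition is what separates fusion from a departing
visitor: a visitor leaving the field produces the same single-frame
intensity loss as fast fusion, but never accumulates 40 confined frames.

Release duration is measured on the ΔF trace in two steps:

1. **Qualification.** The trace must contain a significant loss: a frame at
   the preceding plateau level followed by a one- or two-frame drop larger
   than the standard deviation of the preceding window (default 10 frames).
   Traces without such a drop return a `no_release` sentinel; the onset
   search is restricted to the span where the punctum was actually present.
2. **Localization.** Time 0 (the bright point just before the loss) and the
   release end (return to the background ΔF level) are placed by a
   least-squares changepoint fit of a three-segment model — constant
   plateau, linear ramp to background, constant background — over the decay
   neighbourhood. The fit handles the two phenotypes uniformly: for
   sub-second loss the ramp segment is one or two frames; for multi-second
   loss the ramp's gentle slope (well under one noise sd per frame) is
   exactly the regime where any frame-to-frame drop rule either misses the
   onset or fires on noise, which is why localization is not done by the
   drop rule itself.

Duration is `(end − time0) × frame_interval`. The background ΔF level and
sd come from the median over eight automatically placed non-punctum ROIs in
the same cell (median of several rather than one random ROI, for
robustness). A trace whose fitted end reaches the final frames, or whose
post-end values do not sit within `background_tolerance` (default 2) ×
background sd of the background level, returns `incomplete_decay`.

On the synthetic test surface at SNR 10 and 0.1 s/frame this recovers fast
(0.3–0.8 s) durations within ~1–3 frames and slow (4.5–6.5 s) durations
within ~5 frames, with means 0.59 s and 5.5 s respectively in the
acceptance runs.

## Residence taxonomy

Tracks are linked greedily nearest-neighbour frame to frame (step ≤ max
step per elapsed frame, 1-frame gap tolerance for blinking) — deliberately
the simplest scheme satisfying the confinement criteria, not a LAP/TrackMate
re-implementation. Classification of a track with first frame `f0`, last
frame `f1`, residence `r = f1 − f0 + 1` frames:

* **docking** — confined, reaches the movie end, `r ≥ 40`;
* **undocking** — confined, present at movie start, `r ≥ 40`, leaves;
* **dock-and-undock** — confined, appears and leaves mid-movie, `r ≥ 40`;
* **visiting** — `min_visit ≤ r < 40` (0.59 s ≈ 6 frames at 0.1 s/frame);
* shorter tracks are discarded, not classified; short tracks running into
  the movie end are discarded because their true residence cannot be
  bounded; long unconfined tracks fit no docked class and return None.

A residence of exactly 40 frames classifies on the docked side; visitors
are strictly below 40. The nominal pairing 40 frames ≙ 5.92 s implies a
~148 ms frame interval; the frame count is primary, and a loud warning is
raised whenever `frames × interval` disagrees with the configured seconds
value (as it does at 100 ms/frame).

## Zoning and colocalization

The cell footprint is segmented by Otsu thresholding of the temporal median
projection (transient puncta are suppressed by the median; the threshold is
offset-invariant), keeping the largest component and filling holes; an
externally supplied mask bypasses segmentation but still gets a distance
map. Boundary distance is the Euclidean distance transform × pixel size, so
a mask pixel adjacent to background is one pixel step inside and a 10-pixel
band corresponds to distance ≤ 10 px. A position is peripheral iff its
distance ≤ the band width, default 1.6 µm (10 px at 0.16 µm/px); the band
is specified in µm so the rule transfers across pixel sizes. Zone densities
are normalized to the *total* mask area (per-cell-area convention) and
fractions to the event total.

Colocalization is object-based: a reference punctum is colocalized when
some other-channel punctum centre lies within one pixel — Chebyshev
distance ≤ 1, i.e. the 3×3 neighbourhood, matching a manual one-pixel
centering judgment; Euclidean is selectable. The permutation control
re-places the other channel uniformly over mask pixels and reports the mean
percentage, converging to `100 (1 − (1 − a/N)^n)` for `n` points, `N` mask
pixels and `a` the 9-pixel tolerance neighbourhood.

## Statistics

Group comparisons use the classical pooled-variance unpaired Student's t
with a one-tailed p-value; the direction of the alternative must be stated
by the caller. Welch's form is available behind a flag (the original
analysis does not state whether equal variances were assumed; pooled is the
default reading of "Student's t-test"). Data are summarized as mean ± SEM;
stars follow p < 0.05 (*), < 0.01 (**), < 0.001 (***). Zero variance in
both groups with equal means returns p = 0.5, flagged degenerate. No
multiple-testing correction is applied.

## The synthetic generator

The generator renders one elliptical cell (default 16 × 12 µm in a 256²
field at 0.16 µm/px) as a uniform baseline (default 30 counts) over a
uniform background (20 counts). Puncta are isotropic Gaussians (σ default
0.2 µm, ≈ 1.25 px) evaluated at pixel centres; an isolated punctum's
integral equals `A·2πσ_px²`, used as a render oracle. Noise is Gaussian
read noise (default sd 10 → SNR 10 at the default amplitude 100), with
optional Poisson shot noise and an optional linear bleach flag. Events
follow the behavioural repertoire: docking (persists to movie end),
undocking (present from frame 0), dock-and-undock, visiting (short
residence, mobile), and fusion. Fusion events hold full amplitude for their
docked residence, then ramp linearly to zero over the release duration
(exponential selectable); the ramp shape for slow release is a modelling
choice, since only total durations are reported for the real events, and
linear makes the ground-truth duration unambiguous for recovery tests.
Slow-fusion onsets render a one-frame 1.3× overshoot, mirroring the
fluorescence increase seen at MVB fusion; fast fusion with release ≤ one
frame interval disappears between consecutive frames. Moving classes
perform an isotropic Gaussian random walk (visitors default 0.03 µm/frame;
docked classes immobile by default so the 0.3 µm confinement is guaranteed).

Random schedules place events at mask-pixel centres within a requested zone
(peripheral / non-peripheral / uniform), with exact per-class counts,
reproducible seeds, and a minimum spacing (default 1.5 µm) between events;
static non-event puncta keep ≥ 3.6 × psf σ from each other and from event
sites so the generator does not confound its own ground truth. Zone labels
in the ground-truth log are produced by calling the zoning classifier
itself on the generated mask, so log and classifier agree by construction
and the agreement test guards the plumbing. Release-duration presets are
uniform 0.3–0.8 s (granule-like) and 4.5–6.5 s (MVB-like); per-cell density
presets are normal with means 0.652/0.306 µm⁻² (CD63-like, ND/T2D) and
0.648/0.405 µm⁻² (granule-like), truncated at zero, with a between-cell sd
of 0.12–0.15 µm⁻² chosen as a realistic dispersion (the source data report
means and significance, not spreads).

What the generator does *not* emulate: evanescent-field depth (no axial
dimension — departures are instantaneous disappearances, not gradual
dimming), photobleaching beyond the linear flag, camera gain structure,
multi-cell fields, and organelle shape (all puncta are PSF-limited points).
Passing tests therefore demonstrate correctness of the measurement chain
under these idealized conditions, not robustness to, e.g., z-drift or
uneven illumination in real recordings.

## Numerical choices and degenerate inputs

* Zero-noise traces: SD windows use an ε floor (1e-12) so noise-free step
  traces still qualify.
* Plateau estimates are medians; the qualification scan requires at least
  two window points.
* Ties in plateau maxima and detection merging are broken deterministically
  (top-left pixel; brighter detection wins).
* Sub-pixel positions rounding just outside the rasterized mask are zoned
  through the adjacent rim pixel (< half a pixel of bias); positions
  genuinely outside raise.
* All randomness flows through `numpy` Generators seeded explicitly; the
  pipeline splits one top-level seed per stage, and identical configs
  reproduce every CSV byte-for-byte.

## Problem sizes

The shipped tests and the acceptance script run on 256² movies of 150–400
frames with 10–30 events per movie and 300 permutations for the
colocalization control; these sizes give binomial/Monte-Carlo errors well
inside the asserted tolerances while keeping a full run in the low minutes
on one CPU.

## Known limitations

* Exact ImageJ find-maxima flood-fill equivalence is not promised (plateau
  and edge handling differ in corner cases).
* The release-end estimate inherits a small negative bias for exponential
  ramps fitted by the linear model (~10–20% of the time constant).
* The greedy linker can swap identities when two mobile puncta pass within
  one step of each other; the confinement tests make this harmless for
  docked-class analysis but dense mobile scenes would need a proper LAP
  solver.
* At densities beyond ~1.3 puncta/µm² (0.16 µm/px) the saddle-merge limit
  biases counts low regardless of threshold choice.
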