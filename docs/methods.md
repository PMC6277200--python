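# Methods

This note documents the models, estimators and numerical choices behind
`midgut4d`, and what the synthetic data generator does and does not
emulate.

## Coordinate and data conventions

All analysis happens in physical micrometres in a right-handed space with
x–y the image plane and z the optical axis; frame indices are 0-based and
times are minutes from movie start.  Tabular inputs are plain CSV (schemas
in `midgut4d.io`); image stacks are ImageJ-compatible TIFF carrying the
voxel size, held in memory as `(t, c, z, y, x)` arrays.  The basal plane
of the epithelium is always represented by three annotated reference
points; its unit normal points apically (toward the gut lumen).

## Ring morphometry

The junctional ring of an extruding cell is an ordered list of annotated
3D vertices (typically six).  Its cross-sectional area is the centroid-fan
sum Σ ‖(vᵢ−c)×(vᵢ₊₁−c)‖/2 over adjacent vertex pairs, with c the vertex
centroid — exact for planar convex polygons and well defined for the
slightly non-planar rings real annotations produce.  The footprint is the
orthogonal projection of the vertices onto the basal plane, expressed in a
fixed in-plane orthonormal basis; for a planar ring tilted by θ the
footprint area is the ring area times cos θ.  Signed point-to-plane
distances are the dot product of the plane's unit normal with the vector
from its reference point.

### Ratchet pulse decomposition

Ring closure proceeds by pulses of constriction alternating with pulses of
relaxation or stabilization.  Since no standard segmentation exists for
this signal, the package uses a declared rule: the area series is smoothed
with a centered moving average (default 3 frames), per-interval rates
dA/dt are computed, and intervals are labelled constriction when the rate
falls below −ε, with the dead band ε defaulting to 5% of the maximum
absolute smoothed rate.  Adjacent same-kind intervals merge; residual
segments shorter than 2 frame intervals are absorbed into their
neighbours, so single-frame noise flickers cannot split a pulse and the
returned segments strictly alternate.  Segment mean rates are taken from
the raw series between segment boundaries, so the rate-weighted segment
sum reproduces the net area change exactly, and cumulative constriction
plus relaxation time equals the series span by construction.  At the
study's 5–7.5 min sampling this recovers scheduled pulse counts exactly on
noise-free synthetic closures and within ±1 pulse under 5% area noise,
provided pulses last ≳ 3 frames — closures with more pulses therefore take
proportionally longer (pulses of ~30 min, closures of ~4–12 hr).

### Nuclear travel

Apical nuclear travel is measured on the signed distance of the nuclear
centroid from the basal plane.  The pre-rise baseline is the median of the
first 10 frames; onset requires the smoothed distance to exceed baseline
plus max(2×1.4826×MAD, 0.5 µm) for 2 consecutive frames, and the reported
start is the frame immediately before that excursion (movement is "first
apparent" on the frame the trace departs from).  The peak is the raw
argmax; duration is peak minus start; recoil is peak minus the final
plateau (median of the last 5 frames).  A series with no persistent
excursion is returned as a flagged no-event, not an error.

## Division orientation and the mitotic index

Spindle poles, basal-plane triplets, daughter and enteroblast positions
are annotation inputs (they come from visual inspection in the imaging
workflow, or from the generator's ground truth here).  All axes are
undirected, so every angle is folded into [0°, 90°]:

* horizontal–vertical = 90° minus the angle between the spindle-pole
  vector and the plane normal (0° = in-plane division); the fold makes the
  result independent of pole labelling and of the normal's sign;
* longitudinal–circumferential = angle between the daughter–daughter axis
  and the supplied longitudinal unit vector, after projecting both into
  the epithelial plane when one is given (matching measurement on planar
  projections); the longitudinal axis is an input per mitosis — from tube
  morphology in real data, analytic in synthetic data;
* enteroblast-relative: the reference enteroblast is the sole contacting
  one, or of two the one closer to the mother before division; D1 is the
  daughter closer to the reference; the angle is between the EB→D1 and
  D1→D2 vectors.  Equidistant daughters are flagged as a tie and broken
  deterministically toward the lower index.

Divisions contacting enteroblasts are excluded from horizontal–vertical
and longitudinal–circumferential population summaries, since the
enteroblast contact is itself an orienting cue.  A re-orientation is a
frame-to-frame absolute change of the horizontal–vertical angle at or
above a threshold (15° and 30° reported).

The mitotic index is T_M/T_SC: T_M sums the durations of all observed
mitoses (nuclear condensation to daughter-chromosome decondensation);
T_SC sums, over movies, the stem-cell count at t = 0 times the movie
duration.  Stem counts may be given directly or estimated as 20% of total
nuclei; mid-movie appearances and disappearances of stem cells are
ignored.

## The normalized GFP:RFP fate metric

Within each movie, each channel's raw single-cell intensities are divided
by that channel's maximum over all cells and frames of the movie; the
metric is the per-cell, per-frame ratio of normalized GFP to normalized
RFP.  This cancels any per-movie multiplicative gain exactly and
suppresses depth- and illumination-dependent artifacts that affect both
channels alike.  The literal maximum is used by default (a robust
percentile alternative exists but is off, to match the established
definition); frames with zero RFP are flagged invalid rather than
propagated as infinities.

The pooled progenitor distribution of the metric is bimodal: a sharp low
mode (stem-like cells, reporter off) and a broad high mode (enteroblasts).
The fate threshold is the density minimum between the two highest modes of
a Gaussian kernel density estimate (Silverman bandwidth, values clipped to
[0, 2], grid step 0.001); a unimodal density is an error, not a silent
threshold.  The threshold is imaging-system specific: it is estimated once
from a large pooled distribution and then applied, so downstream analyses
take it as a configured constant (default 0.17) while the per-dataset
estimate is reported alongside.

Benchmark validation: cells observed to divide are stem cells regardless
of reporter level, so the ratios of dividing cells at all frames strictly
before condensation form a benchmark collection; the fraction below
threshold measures how cleanly the threshold separates states.  All
pre-mitotic frames are used (no fixed window).

### Transition calling

A cell transitions to the enteroblast state when its ratio rises
persistently from below to at or above the threshold.  "Persistently"
means 3 consecutive at-or-above frames (default), which rejects
single-frame spikes at 5–15 min sampling.  The crossing frame is the first
frame of the first persistent run.  The baseline is the end of the flat
pre-rise stretch: the lowest trailing-window rolling median (window 6)
before the crossing defines the baseline level, and the baseline frame is
the last pre-crossing frame still at that level within a band set by a
trend-robust noise estimate (1.4826·median|Δ²r|/√6 from second
differences).  On noise-free series this recovers the last flat frame
exactly; under measurement noise the onset lags by a few frames, which
shortens measured transition durations by roughly 10–20% at the
generator's default noise — a known bias of onset detection on slow noisy
ramps.  Transition duration is crossing time minus baseline time.  Cells
entirely above threshold are flagged "already enteroblast"; persistent
falls from above to below are reported as reversion candidates.  Frames
flagged by the bleed-over filter (below) are excluded from calling.

### Contact inference and bleed-over

Sibling contact is inferred from inter-nuclear distance: < 6.0 µm contact,
> 15.5 µm separated, the closed interval [6.0, 15.5] µm indeterminate (the
boundaries are deliberately assigned to the indeterminate class).  The
classification is a total partition of [0, ∞).  Timelines over a pair's
common frames yield: the longest separation run (span from its first to
last frame; ≥ 60 min counts as "separated for at least an hour"),
alternations (state changes between contact and separated after dropping
indeterminate frames and collapsing runs), and a permanent-separation flag
(the last resolved state is separated — trailing indeterminate frames do
not rescue a pair).

When a cell's nucleus collides with a high-reporter neighbour, the
neighbour's GFP bleeds into the cell's measured surface and the ratio
spikes artifactually.  Frames in which a cell lies within 4 µm of a
neighbour whose ratio exceeds 0.5 are marked invalid (retained in output,
excluded from transition calling).

## Segmentation, typing and tracking

Nuclei are segmented by intensity thresholding of the ubiquitous channel —
Otsu per channel per frame by default, fixed thresholds supported for
reproducibility — followed by connected-component labelling
(26-connectivity default; compact nuclei, with a minimum-volume filter
guarding against noise specks) on the physical voxel grid.  Centroids are
intensity-weighted voxel means converted to µm; volumes are voxel count
times voxel volume.  Whole-nucleus typing applies the channel-mask logic
to per-component mean intensities, then the 113 µm³ size filter for
esg-negative nuclei (the boundary value is enteroendocrine).  Watershed
splitting of touching nuclei is out of scope; the synthetic spacing is
chosen so merges are rare.

Tracking links consecutive-frame detections that are mutual nearest
neighbours within a displacement gate (default 5 µm/frame in the library,
3 µm in the imaging round trip), with deterministic (distance, index)
tie-breaking.  This deliberately replaces probabilistic tracking: at 5–15
min sampling nuclear motion is small relative to spacing, the assignment
is unambiguous, and determinism makes every result reproducible.  Gap
closing and automatic mitosis detection are not implemented; daughter
tracks simply begin as new tracks and are associated with mothers through
annotations (ground truth, in synthetic data).  Two progenitors form a
pair at a frame when each is the other's nearest progenitor.

## The synthetic generator

The generator emulates the statistical structure the analyses assume —
not microscopy.  Nuclei live on a cylindrical tube surface (radius 35 µm
default) and follow a bounded random walk in unrolled surface coordinates
(0.25 µm/frame), which keeps the local tangent frame (longitudinal,
circumferential, apical) well defined everywhere.  Cell types follow
exact quotas by default (20% stem, 10% enteroendocrine, 55% enterocyte,
remainder enteroblast) so tests are deterministic; a binomial mode exists.
Enterocyte nuclear volumes are drawn above the 113 µm³ boundary and all
others below it by construction.

Intensities follow `raw = gain × (normalized × channel_base + noise)`: the
per-movie gain differs between movies so cross-movie normalization is
genuinely exercised, and one calibration frame per channel is pinned to
the channel maximum so normalized intensities span exactly [0, 1] and the
realized GFP:RFP of each cell-frame equals its target.  Targets are drawn
from two modes (0.015 and 0.528, the study conditions) for stem-like and
enteroblast cells respectively.  Scheduled events carry complete ground
truth: mitoses place spindle poles on the local tangent frame so scheduled
horizontal–vertical and longitudinal–circumferential angles are exact;
extrusions build piecewise-linear area schedules whose relaxations regain
part of each constriction (mean constriction rate ≈ 1.4× the relaxation
rate, net closure to 2% of initial area) with relaxations of ≥ 3 frame
intervals and constrictions of ≥ 2 so that the pulse decomposition is
identifiable at the sampling rate; transitions are flat-then-linear ratio
ramps crossing the threshold at the scheduled frame; sibling pairs realize
scheduled contact-state sequences as exact inter-nuclear distances (4, 10
and 20 µm for the three states).  Overlapping events on one cell are
rejected rather than merged, keeping ground truth unambiguous.

Rendering draws each nucleus as an isotropic 3D Gaussian whose
half-maximum isosurface encloses the nominal nuclear volume
(σ = r/√(2 ln 2)), added to the channels its type expresses, plus Gaussian
read noise; segmenting at half amplitude then recovers nominal volumes up
to voxelization error.  What the generator does *not* emulate: tissue
movement and registration artifacts, anisotropic PSFs, photobleaching,
nuclear shape variation, touching nuclei, and cell death.  Passing tests
therefore demonstrate correctness of the measurements on data with the
assumed structure, not robustness to raw-microscopy pathologies.

## Problem sizes and reproducibility

The test suite and the acceptance script run synthetic studies at the
scale the analyses were designed for: movies of 40–251 cells and 20–116
frames, 5–7.5 min intervals, 1 µm isotropic voxels for rendered volumes
(~70×70×110 voxels), 18–39 scheduled events per cohort.  These sizes give
every estimator enough data to be measured meaningfully while keeping a
full run in seconds.  All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical configurations give
byte-identical outputs, and the pipeline manifest records config digests
so cached stage outputs are reused only when nothing changed.

## Known limitations

* Pulse decomposition needs pulses of at least ~3 frame intervals; faster
  ratchets at coarse sampling will merge.
* Transition onset detection is biased late (durations short) on noisy
  slow ramps, as quantified above.
* The mutual-nearest-neighbour linker has no gap closing; a missed
  detection splits a track.
* The mode locations returned by the threshold estimator inherit KDE
  smoothing bias; the between-mode minimum (the quantity that matters) is
  much more stable than the mode positions themselves.
* Typing assumes the fate-sensor genotype's containment structure
  (CFP⁺ ⊆ RFP⁺); other marker combinations need their own mask logic.
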