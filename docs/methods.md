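# Methods

This note documents the models, conventions and design choices behind
larvatrack, in the order data flows through the pipeline.

## Coordinates, calibration and features

All geometry uses image convention: x right, y down, origin at the
top-left pixel, 0-based frames and pixels.  A `Calibration` holds the
mm-per-pixel scale factor (from a precomputed value, or from two image
points a known physical distance apart) and the frame rate; lengths
convert with the scale, areas with its square.

Per frame and object, the binary mask yields:

- **polygon** — the sub-pixel outer contour of the largest connected
  foreground component (multiple components in one object mask are a
  segmentation artefact; the largest is kept and the collision-family
  QC rules deal with the consequences downstream);
- **centroid** — the polygon's area centroid (shapely), falling back to
  the vertex mean with a warning for degenerate zero-area polygons;
- **area** — foreground pixel count × scale², i.e. the mask area rather
  than the polygon area (the two differ by half-pixel boundary effects);
- **ellipse** — a least-squares conic fit to the contour.  Axis lengths
  are reported as full lengths (diameters), `major ≥ minor` is enforced
  by swapping axes and rotating the angle by 90° when needed, and the
  angle is axial, in degrees in [0, 180).  Contours with fewer than
  five points are unfittable; such frames keep centroid and area but
  carry NaN ellipse columns and an `undefined` posture state.

## Posture classification

A crawling larva is long and thin; a head-casting larva folds, so the
axis ratio *R* = major/minor drops.  Absolute *R* varies with animal
size, so each track's *R* series is standardised to z-scores using the
mean and *population* standard deviation over **all raw frames of that
track** (the z-score is a raw-frame quantity; QC happens afterwards).
A zero-variance series maps to all-zero z.

The default classifier follows the printed rule *bent ⇔ z ≥ 0.8*
verbatim (`bent_direction="above"`).  Geometrically, however, a bent
body has a *smaller* R, i.e. lies in the lower tail; which tail is
"bent" in a given setup depends on how R is distributed and labelled,
so the direction is a config switch rather than code.  The synthetic
generator gives bent frames low R, making the two conventions
distinguishable: analyses of synthetic scenes therefore run with
`bent_direction="below"`, and the recovery tests confirm that this
convention reproduces the generated head-cast fraction.  The threshold
(0.8 s.d.) and direction are both in `PostureConfig`.

## Error detection and excision

Six failure modes, six detectors, fixed order (the order is part of the
algorithm's semantics and is deliberately not configurable):

1. **static size** — a run of frames with *identical* size longer than
   20 frames means the track froze on background.  Equality is tested
   on raw integer pixel counts, not on derived mm² floats, so "no size
   change" is exact.
2. **segmentation + infill** — flags partition each track into maximal
   inlier/outlier segments; an inlier frame within 20 frames of outlier
   segments on *both* sides is re-flagged (`infill`).
3. **size jump** — a frame-to-frame size step > 1.5 mm² indicates a
   collision merging two animals under one identity.
4. **size drift** — gradual identity transfer during prolonged contact.
   The size series is median-filtered (kernel 201, clamped to the
   largest odd value ≤ track length, reflect-padded), differenced, and
   the difference smoothed (moving average, kernel 11).  An 80-frame
   window is a drift candidate when ≥ 75% of its entries change in the
   same strict direction; overlapping candidate windows merge, and a
   merged region is kept as flagged only when the filtered size at its
   start and end differs by > 1 mm² (regions failing this magnitude
   test are un-flagged).  The implementation is vectorised with
   cumulative sign counts and is tested for exact agreement with a
   brute-force per-window counting oracle.
5. **identity switch** — the first inlier segment with ≥ 200 frames
   sets a baseline median size (if none qualifies the stage is skipped
   with a notice); any other inlier segment whose median differs from
   the baseline by > 1 mm² is flagged in full.  Note this stage can
   only see a switch if earlier stages created a segment boundary; an
   abrupt sustained size shift produces exactly that, because the
   median-filtered transition region is itself drift-flagged.
6. **statistical outliers** — remaining inlier frames more than 4 size
   s.d. or 5 speed s.d. from the mean.  Moments are computed over
   currently-inlier frames only, so corruption caught earlier cannot
   inflate the spread.  (Published descriptions of this family of
   pipelines quote both ±4 and ±5 s.d. for the speed cut; the more
   specific value, 5, is the default and both are configurable.)

Finally, **duplicate tracks**: for each pair, frames whose centroids
lie within 0.5 px ("identical" up to jitter) are counted; above 100
such frames, the track with more flagged frames is removed (tie: the
track is assigned to the first, i.e. lower, object id), and the
coincident region on the survivor is flagged, dilated by the 20-frame
infill radius, since the duplicate's extent is uncertain at its edges.

All threshold comparisons are strict ("more than", "greater than"), and
each boundary is pinned by a test (Δ = 1.4/1.6 mm², runs of 20/21
identical sizes, 90/150 coincident frames, median deltas 0.5/1.5 mm²,
a value exactly 4 s.d. from the mean).

Tracks whose flagged fraction exceeds 1/3 get an omit recommendation in
the summary; nothing is deleted beyond duplicates — the caller decides.

Infilling runs after the static stage and around duplicate regions,
where the flag geometry calls for it; re-running it after every stage
would be a defensible alternative and would only enlarge excised
regions.

## Locomotion metrics

Distance is summed only between temporally *consecutive* retained
frames: gaps left by QC are never bridged, so excising frames can only
shorten a track (a bridging flag exists but defaults to off).  Mean
speed is the mean of the per-frame speeds implied by those steps; frame
0 — and the first frame after any gap — contributes a speed of 0,
which is negligible at assay length (≥ 1,800 frames) and documented
here.  Time-in-state divides good-frame counts by the frame rate.
State-restricted metrics (distance and mean speed while elongated)
simply restrict those sums to elongated frames.  Body length is
approximated by the median ellipse major axis over elongated good
frames — undefined (NaN) for a track with no elongated frame, in which
case the length-normalised metrics are NaN too.

## Reference segmentation backend

The backend contract is minimal: video + one point prompt per object on
an annotation frame → per-frame binary masks with stable identities.
The built-in reference backend is classical: each frame is thresholded
with the triangle method (chosen over Otsu because the animals cover a
tiny fraction of the frame, exactly the regime the triangle heuristic
targets; Otsu is available as an option for genuinely bimodal frames),
connected components are filtered to a plausible area range, prompts
claim their enclosing components on the annotation frame, and
identities propagate forward by greedy nearest-centroid matching under
a maximum match distance (default 5× the mean blob radius at
annotation).  An unmatched identity is absent from that frame; its last
centroid is remembered for re-acquisition.  The backend is
deterministic and propagates forward only; backward propagation and
model-specific memory management (e.g. a bounded inference-state
window) are concerns of foundation-model adapters behind the same
contract.

## Synthetic scenes

`SceneSpec` defaults encode the assay's study conditions: five animals
in a 60 mm circular arena, 180 s at 10 fps, 0.15 mm/px.  Each animal is
an ellipse (4 × 1 mm elongated, R = 4; 2.8 × 1.4 mm bent, R = 2 — two
well-separated R modes) driven by a first-order Markov chain over run
(1 mm/s, typical third-instar crawl), pause and head-cast (0.2 mm/s)
states, with heading diffusion, reflective arena walls, and optional
mutual steer-away for collision-free scenes.  Gaussian noise is added
to positions (0.02 mm), axis lengths (0.05 mm) and areas (0.03 mm²).
Rendering rasterises bright ellipses (220) on a dark disc (30) and
background (10) and returns exact ground-truth masks.

What the generator does **not** emulate: peristaltic shape change
within a run, gradual posture transitions, lighting/contrast
variability, motion blur, reflections, or genuinely ambiguous
collisions.  Passing tests therefore demonstrate the correctness of the
pipeline's logic and its calibrated arithmetic on idealised input — not
segmentation robustness on difficult natural video, which is the
backend adapter's problem.

### Failure injection and detection scoring

`inject_failures` corrupts feature-level tracks with the six failure
signatures and returns exact per-frame truth.  Magnitudes must satisfy
the matching QC trigger (enforced at construction): frozen runs > 20
frames; collision steps > 1.5 mm²; drift ramps and identity-switch
shifts > 1 mm²; duplicates copy > 100 frames of another track's
centroids.  Identity-jump events displace the centroid for one frame
(15 mm), producing a speed spike far beyond 5 s.d.

Detection is scored per event (mirroring per-case curation of real
tracks): an event is detected when ≥ 50% of its frames are flagged for
any reason, or its track is removed as a duplicate; the overlap
fraction is configurable.  The canned experiment
(`run_injection_experiment`, also behind `scripts/acceptance.py` and
the CLI `score` command) simulates independent single-animal tracks of
1,800 frames, injects one event per track cycling through the five
excisable modes, and runs QC per track — duplicate resolution is
meaningless across independently simulated scenes and is exercised
separately.

## Numerical choices and degenerate inputs

- Population (n) standard deviation throughout (z-scores, outlier
  moments); configurable nowhere because the difference is immaterial
  at track lengths the assay produces, but documented here.
- Median/smoothing kernels clamp to the track length (largest odd
  value) with reflect padding; tracks shorter than the drift window
  skip the drift stage with a log notice.
- Ellipse fits that fail (collinear or < 5 contour points) mark the
  frame `undefined` instead of aborting the run.
- Greedy matching ties in the backend resolve by (distance, object id,
  component label) sort order — deterministic.
- Duplicate-outlier ties keep the lower object id.
- Empty good-frame sets yield an all-zero summary with the omit flag.
- CSV round-trips are exact to 6 decimal places (fixed-format floats).

## Problem sizes used in the validation suite

The injection experiment runs at full assay scale (100 tracks × 1,800
frames).  Render-and-recover tests use 60 s scenes (600 frames) of five
animals and 10–30 s scenes elsewhere — long enough for every pipeline
stage (including the 201-frame median filter and 200-frame baselines)
to operate at its real kernel sizes while keeping the suite quick.

## Known limitations

- Collisions are excised, not resolved: no attempt to split merged
  masks or re-assign identities after contact.
- The identity-switch stage is blind to a switch that leaves no size
  signature at all (two identically sized animals) — as is any
  size-based detector.
- Body length from the ellipse major axis underestimates the true
  contour length of a curled animal; it is only used on elongated
  frames, where the bias is small.
- The reference backend assumes bright animals on a darker, roughly
  uniform background; it is a correctness baseline and a test vehicle,
  not a competitor to learned video segmenters on natural footage.
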