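# Methods

## Recording model

A recording is a directory in the export dialect of a head-mounted wearable
tracker: `world_timestamps.csv` (the temporal reference for the scene
video), `gaze.csv` (2-D gaze in scene pixels with a confidence value),
`3d_eye_states.csv` (pupil diameter per eye in millimetres), `events.csv`
(session markers), and four optional streams (`fixations`, `saccades`,
`blinks`, `imu`) that are parsed and retained but not analyzed. Scene frames
are an ordered directory of PNG/JPEG images. Header spellings drift across
export versions, so each stream resolves its columns through a configurable
dialect map (the current cloud-export headers and a minimal
`timestamp,x,y,confidence` dialect are built in; `worn` is accepted as a
confidence stand-in).

Timestamps are converted to int64 nanoseconds on read (float inputs below
10^12 are interpreted as seconds). Integer time makes the alignment step
exactly reproducible — no float-equality edge cases. When both eyes report a
pupil diameter the two are averaged into a single per-sample value; a
missing value stays NaN and is never conflated with zero.

## Temporal alignment

All streams are fused onto the scene-frame timeline, the slowest clock
(30 Hz default). Each frame takes the gaze sample and eye-state sample with
minimal |Δt|, accepted only if |Δt| ≤ tolerance. The tolerance defaults to
half the frame period (≈16.7 ms at 30 Hz): a sample farther than half a
frame from every frame timestamp belongs to no frame. Nearest-neighbour
matching is used rather than interpolation — pupil diameter in particular is
never interpolated across gaps, since dilation dynamics are exactly what the
downstream statistics measure. Ties in |Δt| break toward the earlier sample,
for determinism. Missing data never drops a frame; the field is left NaN and
the frame keeps its row.

Gaze pixels are normalized by the scene dimensions. Off-frame gaze is kept
un-clamped (flagged `on_frame=False`) so quality control can see it, but it
never participates in AOI tests.

## Dynamic areas of interest and team assignment

Per frame: detect persons → test whether the gaze pixel lies in a box →
crop the chosen box → segment upper clothing → multiply the binary mask
into the crop → take the channel-wise median color of the mask support →
classify against the palette. When the gaze lies in several boxes the
smallest-area box wins (the most specific AOI), ties broken by detector
confidence then listing order. Any per-frame failure degrades that single
frame to `unknown` (AOI hit stood) or `none` (no hit) and the run continues.

The median is used for color dominance because jersey numbers and trim are
minority pixels; it is robust where a mean would blend them in. Matching
happens in CIELAB (sRGB → Lab, D65): the nearer reference is assigned if
its ΔE\*ab (CIE76) is within `match_threshold` (default 25). Otherwise a
light/dark fallback applies: L\* above `lightness_split` (default 50) maps
to the team whose *reference* is lighter, below to the darker team, and a
dead band of ±5 L\* units returns `unknown`. Tying the fallback to the
references' lightness rather than to a fixed label makes classification
symmetric under swapping the palette — a property the tests assert on
random colors. Observations supported by fewer than `min_pixels` (default
25) mask pixels return `unknown`: tiny crops near the system's useful range
limit (~15 m) carry unreliable color. The two-stage rule (known-color match
with a light/dark fallback) is this package's own concrete design for the
classification contract; the default palette is white (Team A) vs navy
(Team B), loadable from YAML.

Detector and segmenter sit behind minimal contracts (`detect(frame,
frame_index)` → boxes; `segment(patch)` → binary mask). Production backends
would be pretrained person-detection and clothes-segmentation networks; the
package ships deterministic mocks that replay ground-truth sidecars, because
the pipeline around the models — not the model weights — is what this
package contributes and tests. Boxes are half-open integer rectangles,
clipped to the frame; masks must match their crop's geometry exactly.

## Gaze events and the feature table

"Number of gazes" is operationalized as gaze **events**: maximal runs of
consecutive frames carrying the same team label, with runs shorter than
`min_event_frames` (default 2 frames ≈ 67 ms at 30 Hz) discarded as
detection flicker; `unknown`/`none` frames break runs. Raw frame counts are
reported alongside, so analyses preferring a dwell-time-like unit have it.

Phase annotations are spans `[start_ts, end_ts)` with an attacking team.
The phase of an *observed* team inside a span is derived: attack if it is
the attacking team, defense otherwise. The feature table accumulates, per
(observed team × phase): event count (an event belongs to the phase of its
start frame), frame count, and the mean and sample s.d. of the pupil
diameters of those frames (missing diameters excluded; pooled across
frames, not per-event first). `Total` rows per phase sum the counts and
pool the diameters across teams. Empty cells report zero counts and NaN
pupil statistics.

## Statistics

Welch's unpaired two-sided t-test is the default observer comparison
(Student's optional); the statistic and Welch–Satterthwaite df are computed
in closed form, with scipy supplying only the t distribution. Identical
samples return t = 0, p = 1; degenerate inputs raise with the condition
named. Significance marking uses p ≤ α (α = 0.05 default).

The coach analysis is a 2×2 mixed-design ANOVA: game phase within-subjects,
coach between-subjects, the annotated clip being the subject/observation
unit. The classical decomposition is computed from cell, subject, and group
means: the between effect is tested against subjects-within-groups
(df = N−2 for two groups) and the phase and interaction effects against the
phase×subject residual (also df = N−2 with two phase levels). All three
effects are reported. Zero error sums of squares (e.g. all values equal)
are flagged degenerate and reported as F = 0, p = 1 by convention rather
than raising. Tests cross-check every statistic against independent
reference implementations to 1e-8 and against a brute-force sums-of-squares
oracle.

No multiple-testing correction is applied by default, matching the
preliminary character of the study design this serves.

## Synthetic data generator

The generator emulates the acquisition geometry: a 1600×1200 @ 30 Hz scene
camera and a 200 Hz eye stream (both configurable), white vs navy jerseys,
and clips from a few seconds up to minutes. Players are solid rectangles in
disjoint motion lanes (so boxes never overlap and the intended gaze target
is unambiguous); the top half of each player box is the jersey — which
gives the mock segmenter an exact geometric definition of "upper clothing"
— and the bottom half is neutral shorts over a uniform court color. The
scripted gaze targets player centroids or a background anchor in spans of
4–8 frames, sampled on the 200 Hz grid, with optional Gaussian pixel noise
and sample dropout. Pupil diameter is baseline 3.6 mm plus a +0.3 mm shift
while the observer's own team defends plus 0.05 mm Gaussian noise — the
direction and order of magnitude of defensive-phase pupil dilation in this
setting. Every quantity the pipeline should recover is also written to a
ground-truth sidecar computed by direct recounting, independent of the
pipeline code paths it validates.

What the generator deliberately does **not** model: occlusion, photometric
variation (glare, shadows), camera motion, detector/segmenter error
statistics, or crowded scenes. Passing end-to-end tests therefore
demonstrates that the *pipeline logic* is exact — alignment, AOI choice,
mask arithmetic, color classification, aggregation — not that real-world
perception models would be error-free.

For statistical calibration a separate Gaussian generator draws balanced
2 (coach) × n (subjects) × 2 (phase) long-format datasets as subject
intercept + fixed effects + residual. Subject and residual variances take
equal shares of a unit total variance (intra-class correlation 0.5 —
per-subject pupil baselines are stable relative to within-subject noise),
and effect sizes are expressed in units of the total s.d.; a 1.0 s.d.
phase shift then has analytic within-F power ≈ 0.96 at n = 8 per group
(noncentral F(1, 14), λ = 16), which the test suite verifies against a
direct power oracle alongside the simulated rejection rate.

## Problem sizes and numerical choices

The shipped tests run synthetic scenes at 480×360 or 320×240 with 60–900
frames — enough to exercise the 30/200 Hz rate structure, lane motion, and
multi-segment phase plans while keeping the suite fast; the geometry scales
linearly to the full 1600×1200 device. Calibration simulations use 2000
(null) and 500 (power) replicates at n = 8 subjects per coach. All
generators are pure functions of their seed; CSV output is byte-identical
across reruns.

Known limitations: two teams only; no illumination correction or white
balance; no clock-drift correction across devices (single-device timestamps
assumed coherent); fixation/saccade streams are parsed but not used as an
alternative gaze-event definition; and the gaze-event unit, while the
natural reading of "gaze count" at these magnitudes, is one of several
defensible operationalizations — frame counts are emitted so the choice is
auditable.
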