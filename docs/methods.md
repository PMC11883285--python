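# Methods

`geotrack` reconstructs per-fly trajectories from backlit videos of
*Drosophila* negative-geotaxis (startle-and-climb) assays and computes
behavioral metrics from them. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Detection

**Background model.** Each vial video gets a static background: the
per-pixel median over all frames (midpoint mean for even counts). Flies
move during a trial, so the median at any pixel is the clean backlight;
anything static for more than half the video (wall smudges, glue spots)
is absorbed into the background and deliberately ignored.

**Segmentation.** Flies are dark on a bright field, so a pixel is
foreground when `background − frame > 0.06` (normalized intensity in
[0, 1]; the 0.06 threshold is inclusive on the background side and is
configurable as `diff_threshold`). Frames are segmented independently —
no temporal smoothing — and connected components are taken 8-connected
by default.

**Measurement.** Each component is measured by its pixel-mean centroid,
pixel area, and the axis lengths of the ellipse with the same second
central moments. The ellipse-equivalent axes are an approximation to
calipers-style shortest/longest chords; for fly-shaped blobs the two
agree to within a few percent, and only the minor/major *ratio* is used
downstream.

**Calibration and classification.** A labeled sample of segmented
objects (`single`, `multi`, `noise`) defines the thresholds:

- `area_min_px` — the 16th percentile of single-fly areas (linear
  interpolation between order statistics; the percentile is
  configurable). Anything smaller is noise. This deliberately sacrifices
  the smallest ~16% of true single-fly detections to suppress
  speck-sized noise; the tracker's coasting absorbs the resulting brief
  dropouts.
- `area_single_max_px` — the largest single-fly area; the boundary
  between the single and multi classes (boundary values belong to the
  fly classes: equality with `area_min_px` or `area_single_max_px` is
  single, with `area_multi_max_px` is multi).
- `area_multi_max_px` — the largest multi-fly area; anything larger is
  noise.
- per-class minor/major axis-ratio intervals — the observed [min, max]
  per class (an optional symmetric trim fraction is exposed but defaults
  to 0). An object whose area lands in a class but whose ratio falls
  outside that class's interval is demoted to noise.

A multi-class blob of area `A` stands for `k = ceil(A /
area_single_max_px)` flies (an exact integer quotient stays at that
integer; a small epsilon guards against float round-off), all placed at
the shared blob centroid. After this step every detection represents one
fly.

## Tracking

**State model.** Each fly carries a constant-velocity Kalman filter with
state (x, y, vx, vy) in pixels and pixels/frame. Process noise is a
discrete white-acceleration model (default 1 px/frame² std), measurement
noise defaults to 1 px std, and the initial velocity is zero with a
large (100 px/frame std) variance so early predictions stay near the
first detection. These defaults are not critical: association is
protected by the previous-position fallback below.

**Association cost.** For every (track, detection) pair two distances
are computed: `d_pred`, detection to the Kalman prediction, and
`d_prev`, detection to the track's last known coordinates. The cost
entry is `min(d_pred, d_prev)` by default. Fly motion is erratic —
stops, reversals, startle jumps — and a pure prediction cost misassigns
after every stop; the minimum rule lets the prediction carry moving
flies and the last-known position carry stationary ones. `mean` and
`pred` rules are available (`cost_rule`) for ablation.

**Cost of non-assignment (CON).** The T×D cost block is padded to a
(T+D)-square matrix with the constant CON everywhere outside the real
block. With uniform padding, an isolated track–detection pair is matched
exactly when its distance is below CON, so CON is literally the distance
threshold above which association is rejected. The Hungarian solver
(`scipy.optimize.linear_sum_assignment`) gives the exact minimum-cost
perfect matching; a brute-force permutation oracle cross-checks it in
the tests. CON defaults to 11 px; the synthetic sweep (below) shows the
characteristic U-shaped error around an interior optimum.

**Track management.** The vial's occupancy `n_flies` is known, and the
tracker uses it:

- Assigned tracks take the detection as a Kalman measurement and record
  it.
- Unassigned tracks *coast*: the recorded coordinate repeats the last
  known position (flies that disappear are overwhelmingly stationary or
  occluded, so holding position is the best constant guess), while the
  Kalman filter keeps extrapolating unmeasured. This dual behavior is
  why the cost combines two distances: a moving fly that skipped a frame
  is recaptured through `d_pred`, a stationary one through `d_prev`.
- Unassigned detections found new tracks only while fewer than `n_flies`
  tracks exist; surplus detections are discarded farthest-first from the
  unassigned tracks' previous coordinates (ties broken by detection
  index).
- A track invisible for more than `lost_after_frames` (default 6, i.e.
  0.2 s at 30 Hz) becomes *reacquirable*: a leftover unassigned
  detection may re-seed it (minimum-total-distance pairing when several
  compete). The Kalman filter restarts at the detection but the row
  identity is kept. This is how a fly is picked up again after a drop
  larger than CON — a slip of one body length (≈22 px) already exceeds
  CON = 11, so no drop can ever be followed by direct association. The
  recorded coordinates then show the drop as one large frame-pair
  displacement (coasted pre-drop position → landing), which is exactly
  the signal the slip/fall analytics consume. Without reacquisition a
  dropped fly would coast forever and large drops could never appear in
  a coordinate matrix. The window must exceed typical occlusion
  dropouts (1–3 frames here) and stay well under the post-drop pause of
  a real fly; 6 frames sits comfortably between.
- At finalization each track's pre-birth frames are backfilled with its
  first known position, and any fly never seen at all is emitted as a
  constant track at a uniform-random coordinate in the bottom 5% of the
  ROI (undetected flies overwhelmingly sit at the vial bottom), seeded
  by `rng_seed`. Exactly `n_flies` rows always come out.

Identity switches between colliding flies are tolerated, not repaired:
the analytics treat flies anonymously, so a label swap costs nothing
downstream.

## Analytics

All metrics work in vial coordinates: `x_mm = x_px / px_per_mm`,
`y_mm = (roi_height − y_px) / px_per_mm` (y up, origin at the vial
bottom). The default scale is 4.85 px/mm. The image→physics flip happens
in exactly one function (`to_physical`).

- **Displacement/speed/angle.** Per frame pair, `Δr` (mm), `s = Δr/Δt`
  (mm/s) and `θ = atan2(Δy, |Δx|)` in degrees, range (−90°, 90°]:
  folding the sign of Δx makes left and right indistinguishable, so θ
  only encodes up (+) vs down (−). θ is undefined (NaN) for a
  stationary pair. Pairs with `Δr ≥ 4 mm` are gated out of the
  speed–angle data as artifactual (jumps, slips, falls, in-vial
  flight); the gate is inclusive. Average speed is the mean over
  non-gated pairs (gated pairs are omitted, not zero-filled; stationary
  pairs contribute zeros); average angle is the mean over defined θ.
- **Climbing curves.** Per fly, the time of the *first* frame strictly
  above a target height, counted once even if the fly later descends.
  Per trial this gives a unit-step staircase; across trials the mean
  curve (steps of 1/N_trials) with an s.e.m. band, both evaluated on
  the union of step times (right-continuous).
- **Turning rate.** Non-zero changes of θ between consecutive defined
  pairs (tolerance 1e-6 degrees — "non-zero" taken literally on
  quantized data), divided by the trajectory duration. An undefined-θ
  pair breaks the chain. This measures track-direction turns, not body
  heading.
- **Slips and falls.** A frame-pair height loss `−Δy` in [4.5, 12] mm
  (about one to three body lengths) is a slip; `> 12 mm` is a fall
  (both bounds inclusive on the slip side). Each event records the
  pre-drop height and the ratio of the drop to the maximum possible
  drop from that height (1 = fell to the bottom). Any drop ≥ 4.5 mm
  necessarily exceeds the 4 mm gate, so drop events and speed–angle
  pairs are disjoint by construction.
- **Directional-bias ratio ρ+/ρ−.** Speed–angle pairs are resampled
  with replacement (N_sample = data size), split by the sign of θ, and
  Spearman-correlated per stratum (average ranks for ties); the ratio
  ρ+/ρ− is recorded per replicate (default 1000). Replicates where a
  stratum has fewer than 3 pairs, a coefficient is undefined, or
  ρ− = 0 are discarded and counted rather than imputed — the reported
  mean ± sd is over surviving replicates, and a large discard count
  flags an unreliable ratio.
- **Group summaries.** Nested group → fly structure with
  `resolve("Group(i).Fly_no(j).Field")`-style 1-based access mirroring
  the field's conventional analysis structure, plus JSON export.

## Synthetic validation

The `synthetic` module is the package's measurement instrument: it
generates trajectories with a known script, renders them into videos the
real pipeline can ingest, and scores tracking output.

**Walk model.** Each fly runs a state machine (climb, pause, slip,
fall). Climbing steps follow a clipped-normal speed (default mean
20 mm/s, sd 8 — a vigorous wildtype pace) along a heading that mixes
persistence (0.7), a pull toward straight up (0.55), and Gaussian
angular noise (25°). Pauses start at 2%/frame and last ~12 frames.
Slips displace the fly down by uniform 4.5–12 mm in a single frame
pair, falls by uniform(12 mm, current height); rates default to 0.002
and 0.0025 per frame-pair (≈4 slips and 5 falls per 7-fly, 10 s video,
matching observed wildtype drop frequencies of roughly 0.5% of frame
pairs). After a drop the fly takes a righting pause of uniform 8–20
frames — flies that lose grip need a moment to right themselves — which
also makes the landing observable to the tracker. Flies reaching the
top mostly rest there (probability 0.9, mean 80 frames). Walls reflect.

**Lanes and collisions.** Real flies disperse around the vial
circumference, so in a 2-D projection each keeps loosely to a vertical
lane (`lane_pull`, an Ornstein–Uhlenbeck-style pull toward a per-fly x
anchor). The pull strength is the knob controlling how often two flies
overlap into one blob; the default (0.19, with the 170 px ROI width and
the top-rest behavior) yields ≈3–4% of frames containing an overlapping
pair, the collision regime of a standard 7-fly vial.

**Rendering.** Flies are dark (0.35) anti-aliased filled ellipses,
oriented along the heading, on a bright (≈0.9) field with a gentle
illumination gradient. Apparent body size fluctuates frame to frame
(7% multiplicative jitter — posture, pitch, distance from the wall), so
dips below the calibrated 16% area floor are transient rather than
permanent, as in real footage. Overlapping flies merge into one blob.
Optional aberrations: flickering fly-sized "shadows" anchored near a
fly, and fixed-position flickering specks that stay out of the median
background.

**Calibration twin.** `synthetic_calibration` renders isolated flies,
merged 2–4 fly clusters, specks and streaks, measures them through the
same segmentation as tracking, and labels them — so derived thresholds
see exactly the areas the detector will.

**Evaluator.** Tracked and true positions are matched per frame by
minimum-total-distance assignment (accuracy is identity-agnostic;
cost-equal matchings resolve in favor of the previous frame so merged
blobs don't flip arbitrarily). A position is correct within 10 px
(≈2 mm). Identity switches are frames whose matching changed, over
n−1 transitions. The missing-coordinate rate is the fraction of
entries not backed by a detection; the large-jump statistic averages
each track's top 1% frame-to-frame displacements normalized to vial
length; their weighted sum (1 and 0.1) is the CON-sweep objective.

**CON-sweep benchmark.** `con_sweep_params` fixes a deliberately
adversarial scene: slow movers (9 ± 4 mm/s, a sluggish-strain pace that
keeps the reconnection benefit of large CON bounded), drops disabled
(so the jump statistic reflects assignment errors, not genuine falls),
and 10 static flicker specks (standing traps for an over-generous CON).
Averaged over six seeded videos, the weighted error is high at CON ≤ 2
(genuine displacements rejected), minimal near CON ≈ 8, and rises
beyond (speck captures): an interior optimum consistent with the
package's default operating range.

**What the synthetic tests show — and don't.** Passing the benchmark
(≥97% of positions within 10 px, ~0.5 px localization, <2% switch
frames over ten 7-fly videos) demonstrates the pipeline's logic:
calibration-driven classification, merged-blob splitting, occlusion
coasting, and drop reacquisition all work as designed under the modeled
conditions. The generator does not emulate perspective distortion,
off-wall (3-D) flight, legs/wings breaking the elliptical silhouette,
reflections off the vial walls, or illumination drift over a trial;
real-footage accuracy therefore still depends on a careful calibration
table and a correct `px_per_mm`, and the 0.5 px synthetic localization
error should be read as a floor, not a forecast.

## Problem sizes and numerical choices

Benchmarks use 7 flies × 300 frames (one 10 s trial at 30 Hz) per
video, 10 videos for the accuracy benchmark and 6 for the CON sweep —
enough trials for stable means while keeping the full validation run in
the low minutes on one core. Bootstrap tests use 5 000 pairs per
stratum and 300–1000 replicates. Coordinates are stored to 2 decimal
pixels; the segmentation threshold carries a 1e-9 slack so a difference
of exactly `diff_threshold` stays background despite float round-off;
ceil-based clone counts use a 1e-9 epsilon so exact multiples don't
produce a phantom fly. All randomness (walks, rendering jitter,
bottom-seeding, bootstrap) flows from explicit integer seeds.

## Known limitations

- Multi-fly blobs give every occupant the shared centroid; during long
  collisions per-fly position error is bounded by the blob radius.
- Identity is not guaranteed through collisions (by design; analyses
  are anonymized).
- The 16% area floor trades the smallest true detections for noise
  rejection; strains much smaller than the calibration sample need a
  fresh calibration table.
- Drops are recorded with a delay of `lost_after_frames` + 1 frames
  (the reacquisition latency); sizes and counts are preserved, exact
  timing is not.
- MP4/AVI decoding requires an imageio-compatible backend; frame
  directories (PNG/TIFF) are always supported.
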