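# Methods

## The generative model: regularity tables

Everything in this package rests on two tables mapping
(factor, BPSD type, severity) to an inclusive integer **level range**.
Severity takes three values — high, mild, none — and the three modeled
BPSD types are agitation (0), apathy (1), depression (2); severity
"none" yields label 3 (no BPSD), so the no-BPSD class is a mixture of
the three types' "none" columns.

Most factors are 4-level ordinals (0 = no change … 3 = drastic change).
Related factors follow a generic scheme — high 2–3, mild 1–3, none 0–1 —
with factor-specific printed rows where the literature is more specific:
MMSE (integer 0–30; high 0–22, mild 22–27, none 27–30), anxiety
(inverted: it *falls* as dementia severity rises), time of day (six
bins), walking speed (slow gait marks dementia: high severity pins level
0, no BPSD spans 2–3), HRV (low in depression, high in agitation),
daytime activity, and wandering (binary, admitted only for depression).
Unrelated factors span 0–2 at every severity unless a printed cell says
otherwise. The tables ship as versioned JSON fixtures; a loader checks
completeness (54 cells each) at import, and a checksum test pins the
transcription.

Two places where the descriptive text and the printed tables disagree
(MMSE mild 22–26 vs 22–27; no-apathy daytime activity 2–3 vs 1–3) are
resolved in favor of the tables.

Discretization uses left-closed, right-open bins (a convention the
printed open intervals with touching endpoints force us to choose):
time (9,12)→0 … (19,21)→4, otherwise 5; speed [0,0.7)→0, [0.7,0.9)→1,
[0.9,1.2)→2, ≥1.2→3 m/s.

## Data generation

Each factor level is drawn independently and uniformly over the integers
of its range, inclusive — uniformity being the minimal reading of "a
random number function". MMSE is sampled inclusively on the printed
ranges, so adjacent severities share the boundary scores 22 and 27; this
overlap is intentional (the ranges themselves overlap in print). The
default composition is 20 high + 10 mild + 10 none per type (120 total);
`default_composition(n)` scales it proportionally for the size study.
Generation is a pure function of (table, composition, seed); test sets
use the same composition with an independent stream.

The PsyCo+HRV variant has no published table of its own: it appends the
HRV row of the sensor-side table to the PsyCo table unchanged.

## Classifiers

All four variants use one recipe: a CART tree grown on Gini impurity
with **at most 20 splits**, implemented as `max_leaf_nodes = 21` (a
binary tree with k internal nodes has k+1 leaves) under scikit-learn's
best-first growth. Other hyperparameters stay at library defaults.
Prediction takes the leaf majority, ties broken toward the smallest
label code. AUC is macro one-vs-rest on leaf class frequencies — the
multiclass scheme is our choice, as none is stated for this model
family. Trees serialize to a plain JSON node list; a pure-Python reload
reproduces predictions exactly.

The **sample-size study** reports 5-fold stratified cross-validation
accuracy and AUC on the training set, not resubstitution: a 21-leaf tree
nearly memorizes 60–480 samples, so resubstitution accuracy starts near
99% and *falls* with n, whereas the cross-validated estimate rises with
n (≈85→91% from n=60 to 480) as leaf statistics stabilize — the behavior
a modeling GUI's displayed "accuracy" shows, and the quantity worth
tracking.

## The virtual home

The 3D game-engine environment of the original platform is replaced by a
2D kinematic world; the exact published room layouts are unavailable, so
the three fixtures are *authored approximations* matching the
qualitative descriptions: room1 large with few occlusions (10×8 m,
following band 1.3–2.1 m), room2 small with more (6×5 m, 1.3–1.8 m),
room3 = room1 plus extra furniture (1.3–2.1 m). Numeric benchmark cells
are therefore indicative; the *patterns* (power ordering, losses rising
with occlusion density) are the reproducible content.

Fixed simulator constants (several of them necessarily our choices, and
documented here as such):

| constant | value | note |
|---|---|---|
| tick | 0.1 s | |
| robot radius / person radius | 0.25 / 0.2 m | disc robot |
| robot speed / turn limits | 1.5 m/s, 2 rad/s | can out-run the fastest target in the open |
| sensor FOV / range | 90° (closed boundary), 5 m | |
| lost threshold | 3 s continuous invisibility | one event per episode |
| end grace after a route | 6 s | settle / re-acquire time |

Line of sight is conservative: a ray that merely grazes a furniture edge
counts as blocked. A robot move that would intersect an obstacle (swept
disc) is refused at contact and logged as a collision; collisions with
the person use the sum of radii. The target walks a constant-speed
polyline; **route corners are chamfered** (0.45 m; 0.3 m on lapping
loops so the path still crosses the marker rectangles) because people
round corners, and an instant 90° vertex would systematically depress a
per-second displacement speed estimate.

## Following controllers

All three stop dead while the target is undetected. Algorithm 1 servos
distance to the middle of the room band and bearing to zero
(proportional gains 2.0 and 3.0 s⁻¹, our documented defaults).
Algorithm 2 idles inside the band, approaching/retreating only outside
it. Algorithm 3 servos toward a fuzzy desired distance with a ±0.25 m
deadband (holding the set-point loosely is what makes it share the band
follower's economy).

The fuzzy controller is Mamdani min–max with centroid defuzzification.
Input universes: speed [0, 1.3] m/s (terms SS/MS/LS) and deviation
[0, 0.5] (SD/MD/LD), where deviation = |bearing| / (FOV/2) × 0.5; output:
distance over the room band with five terms VS…VL. Membership functions
are evenly spaced triangles with saturating shoulders (no break points
are published, so even spacing is the neutral choice), and the 3×3 rule
table is the monotone one the qualitative description dictates: output
term index = 4 − speed term − deviation term. The surface is bounded by
the band, continuous, and monotone non-increasing in both inputs
(property-tested on a grid).

## Perception

Position is triangulated from the robot pose and the range/bearing
reading along the world-frame ray at (heading + bearing). Speed samples
at 1 Hz as the displacement between consecutive position estimates;
gaps longer than 1.5 s (occlusion) restart the 5-sample smoothing
window. The run-level speed judgement is the **median** of the smoothed
values — robust to the rest after a route ends and to turn transients —
then discretized. Wandering uses ordered marker rectangles (0.5 m
squares) at the lapping-loop corners or the pacing endpoints: one
"circle" = one in-order traversal of all rectangles, four circles flag
wandering, and out-of-order entries restart the sequence without ever
incrementing. For pacing (2 rectangles) four circles amount to two full
back-and-forth round trips; scripted wandering runs walk 5 laps /
10 traversals so the detector has margin.

## Experiments

**Following benchmark** — per room and algorithm, the daily-living route
at ten speeds (0.6–1.2 m/s); metrics: power consumption rate
(robot/target distance), speed-detection MAE against the scripted speed
over the walking phase, summed lost episodes and collisions.

**Identification experiment** — a 120-sample BePhyEn test set dealt
round-robin over the rooms (40 each). Speed levels are realized as
representative m/s values (level 0 → 0.5/0.55/0.6, 1 → 0.8, 2 → 1.0/1.1,
3 → 1.2/1.25); wandering=1 becomes the room's scripted wandering route
(lapping in room1, pacing in rooms 2–3); time, environmental change,
HRV, and daytime activity pass through as assumed-known context. A run
is **lost** when no speed judgement could be formed or the robot is not
tracking when the scenario ends (trailing invisibility ≥ 3 s); transient
occlusions the robot recovers from count as lost *episodes* in the
benchmark but do not void an identification run. Lost runs count as
failures in the overall accuracy (an `accuracy_excluding_lost` is also
reported).

## What the synthetic world does and does not show

The generator reproduces the published study conditions exactly
(compositions, ranges, ten speeds, three rooms), so passing tests show
the method chain is faithful and internally consistent. It does not
model sensor noise by default (optional Gaussian noise on distance and
bearing is available in `SimConfig`), comorbid BPSD, irregular gait, or
real HRV measurement — the detection MAEs here are consequently smaller
than a physical platform would show, and room-level loss/collision
counts depend on the authored geometry. Typical end-to-end accuracy is
≈78–83% across seeds, limited about equally by class-range overlap in
the generative tables and by speed misreads through pacing reversals.

## Known limitations

- Pure pursuit with no path planning: the robot cannot follow a loop
  that encloses furniture (the lapping circuit is therefore on open
  floor, as a circle route would be).
- Pacing speed reads bias low near reversals; at 1.0–1.1 m/s the
  detected level often drops to 1, mirroring the failure mode reported
  for pacing detection.
- The held-out accuracy of the HRV-less sensor model replicates ~4 pp
  below its printed value (a single-draw figure); all other headline
  quantities replicate within ~1–3 pp.
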