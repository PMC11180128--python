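# Methods

## Gas model

The chamber is treated as a binary blend of ambient air and the flush gas
(He or N₂), with the measured O₂ partial pressure as the sole proxy for
composition: air mole fraction `f = pO₂ / 210 mbar`, clipped to [0, 1].
Component densities are ideal-gas values `ρ = P·M/(R·T)` evaluated at
273.15 K and 1013.25 hPa with molar masses He 4.0026, N₂ 28.0134, dry air
28.964 g/mol; the mixture density is `f·ρ_air + (1−f)·ρ_flush`, which under
the ideal-gas law is exactly the mole-fraction-weighted molar mass.  Water
vapor is ignored and argon is folded into the air pseudo-species.  The
reference convention (0 °C, 1 atm, 210 mbar ambient O₂) is the simple choice
that reproduces all reported density values to two decimals; temperature,
pressure, and ambient pO₂ are all overridable.

Flight ceilings use the troposphere branch of the International Standard
Atmosphere (sea level 1.225 kg/m³, 288.15 K, lapse 6.5 K/km, `R_s` 287.05
J/(kg·K)), inverted in closed form.  Altitudes above 11 km are rejected
rather than extended into the isothermal layer; no in-scope density requires
them.  The round trip altitude → density → altitude is exact to well under
1 m across the whole troposphere.

## Synthetic assay generator

The generator emulates the experimental protocol at desk scale so that the
full chain — stereo reconstruction, tracking, classification, thresholds —
is testable end to end.

**O₂ time course.**  Deterministic closed form: exponential flush from
ambient (210 mbar) to 1 mbar over 20 s, then first-order relaxation back to
ambient.  Default recovery rates are 0.010 s⁻¹ for He and 0.005 s⁻¹ for N₂ —
helium escapes the bottle faster, so its runs recover sooner.  Default runs
last 180 s sampled at 1 Hz: a deliberate time compression of the hours-long
bench experiment that preserves its structure (flush, deep hypoxia,
monotone recovery through every behavioral gate) while keeping a simulated
replicate at around 15 s of compute.

**Bottle and cameras.**  The flask is modeled as an axis-aligned box
(default 11 × 7 × 23 cm, origin at the floor center, z up) — the canted neck
is irrelevant to wall-proximity logic.  Two ideal pinhole cameras (1000 px
focal, 1920×1080) sit 0.45 m from the bottle axis at 90° vergence, as in a
two-webcam rig.  Camera A runs on the nominal 30 fps clock; camera B's
timestamps are jittered per frame by up to 8 ms, within the 10 ms pairing
tolerance.  Detections get Gaussian pixel noise (default σ = 0.5 px),
independent dropout (5%), and Poisson false positives uniform over the image
(0.2 per frame per camera).  The bottle is shaken for 1 s every 60 s; frames
in shake windows are flagged and must be discarded downstream (motion blur
is not rendered).

**Fly behavior.**  Each fly is a point following a stage machine gated
exactly the way the assay is analyzed: below 33 mbar O₂ it is immobile (A);
above, it walks toward a wall at 1 cm/s (B) and climbs at 1.2 cm/s (C).
From the wall, while the mixture density is below the flight gate
(default 0.93 kg/m³), a per-frame hazard (0.03) launches ballistic jumps at
0.8 m/s — plain jumps (D, deceleration `g`) or wing-assisted jumps (E,
effective deceleration drawn uniformly in (0.2 g, 0.8 g)); at or above the
gate, a hazard (0.05) launches powered flight (F).  In N₂ runs the density
never leaves the gate's neighborhood, so D/E never occur and flies pass
straight from climbing to flight — the behavioral asymmetry the assay is
designed to expose.  Stage transitions are stochastic hazards because the
real behaviors are occasional, not deterministic.  Body length defaults to
2.5 mm (typical for *D. melanogaster*).

A powered-flight path is a closed-form approach / hover-loop / landing
sequence.  The hover loop superposes a horizontal ellipse with a gentle
vertical sinusoid (amplitude 3 cm, 1 Hz), giving |z̈| ≤ 1.2 m/s².  This
choice encodes the physics of hovering — lift approximately cancels weight —
and has a useful analytic consequence: no sub-window of a flight path ever
exhibits the vertical curvature of a ballistic arc, so even a fragment of a
flight track cannot be mistaken for a jump.  The full path still deviates
from any single parabola by far more than the classifier threshold.

What the generator does **not** emulate: fly bodies and postures (points
only), wing kinematics, fly–fly interactions and collisions, lens
distortion, rolling shutter, motion blur during shakes, O₂ gradients inside
the bottle, and sensor lag.  Passing tests therefore validate the
reconstruction/classification logic under controlled noise, not detector
performance on real imagery.

## Stereo reconstruction

Frames are paired across cameras by nearest timestamp within 10 ms (greedy
on |Δt|, pairs disjoint), shake-flagged pairs are rejected, and every
detection in camera A is triangulated against every detection in camera B.
A candidate's 3D point is the midpoint of the common perpendicular of the
two back-projected rays; its reprojection error is the mean pixel distance
of the point's reprojections from the two detections.  Candidates with
error above 3 px (configurable; ray angles under 0.1° are degenerate) are
discarded, the rest resolved one-to-one greedily in increasing error order.
An optimal-assignment reference (`min_cost_match`, Hungarian algorithm) is
kept for cross-checks; at assay densities the greedy result matches it in
well over 95% of frames.  Accepted points must also lie inside the bottle
box dilated by 1 cm — flies live in the bottle, so exterior points are ghost
matches (epipolar coincidences), which this filter removes cheaply.

## Tracking

Two-pass nearest-neighbor linking with gap memory (default 3 frames).
Pass 1 uses a 4 mm/frame radius; tracks with at least two points whose
maximum speed stays at or below 2 cm/s are emitted as *slow* (crawlers) and
removed.  Pass 2 links the remainder with a 60 mm/frame radius and emits
*fast* tracks.  The fast radius must cover free fall from the top of the
bottle (~1.8 m/s ≈ 60 mm/frame at 30 fps), not merely level flight
(~0.3 m/s); a 30 mm radius silently drops every falling point and with it
the jump stages.  Assignment is greedy by distance with one-to-one use per
frame; no motion model is used, so identity swaps between crossing flies are
possible and are handled downstream.

## Behavior classification

Tracks are segmented into maximal runs of a wall state (on-floor, on-wall,
free-space; surface band = 5 mm).  Surface runs are split into immobile and
moving stretches using net displacement over a trailing 1 s window
(≥ 1 body length = moving; positions median-filtered over 3 frames first so
a single mislocalized point cannot fake an onset), then labeled A
(immobile), B (walking: displacement on the floor, or on a wall without
upward progress), or C (climbing: wall displacement with net upward
progress).  Free-space runs pass the rapid-movement filter (maximum
inter-frame speed ≥ 5 cm/s; stationary "free" points are mislocalized wall
flies) and are fit with the ballistic model; the label follows the fitted
effective vertical deceleration `g_eff` and the fit residual: residual above
15% of the segment's vertical extent → F; otherwise `g_eff ≤ 0.2 g` → F,
`< 0.8 g` → E, else D.

Around this core sits an event-vetting layer that rejects the failure modes
of point tracking rather than of flies.  Each rule encodes a physical
constraint:

* **Implied-thrust splitting.**  Anything airborne obeys `a = thrust − g`,
  and a fly's thrust is bounded (~1.5 g).  Free *and* surface runs are split
  wherever the discrete `|a + g ẑ|` exceeds 15 m/s²: such a step is an
  identity swap between two flies or an unobserved surface contact, and the
  two sides must not be fit as one trajectory.  Runs are also split at
  temporal gaps whose flanking points sit within 2 surface bands of a wall
  (the fly plausibly touched down unobserved).
* **Spike rejection.**  Single gross outliers (> 3 mm and > 4× the median
  fit residual, at most 20% of a segment) are dropped before fitting; clean
  segments pass through bit-identically, so exact fits stay exact.
* **Minimum information.**  Classification needs ≥ 6 frames (curvature is
  unmeasurable below that at 30 fps and sub-mm noise) and a `g_eff`
  standard error (from the fit covariance) ≤ 1.5 m/s²; claiming *powered
  flight by non-parabolicity* needs ≥ 10 frames, since flight is sustained
  and sub-second non-parabolic snippets are exactly what corrupted segments
  look like.  The segmentation floor of 4 frames is retained for segment
  bookkeeping.
* **Parabola consistency is absolute as well as relative.**  A genuine arc
  fits to localization-noise level, so "parabola-consistent" requires the
  residual to be under 3 mm in addition to under 15% of the vertical extent;
  large chimeric arcs otherwise slip under the purely relative bound.
* **Launch speed.**  A jump is an impulsive leg-push launch (~0.5–0.8 m/s
  vertically).  D/E labels require the fitted vertical speed at the segment
  start or end to reach 0.45 m/s; flight fragments never exceed ~0.35 m/s
  vertically by construction of hovering.
* **Flight is smooth and fast.**  Residual-route F additionally requires a
  median inter-frame speed ≥ 5 cm/s and directional persistence (mean cosine
  between consecutive displacement directions ≥ 0.2); zigzag or
  mostly-stationary segments are linker cross-talk.
* **Surface behavior is sustained and directed.**  Moving surface runs must
  last ≥ 8 frames and have net/path displacement ratio ≥ 0.2.
* **Hover-F needs confident curvature.**  Curvature-route F requires
  `g_eff + 2·SE ≤ 0.2 g`; a fit straddling the band edge is conservatively
  an assisted jump.

The D-versus-E distinction is purely kinematic here (the effective-gravity
band), whereas an observer with wing imagery could separate them visually;
the band edges (0.2 g, 0.8 g) and the residual fraction (15%) were chosen to
separate the three simulated regimes with margin and are configurable.  The
uncovered surface case — displacement on a wall without upward progress
(e.g. walking on the ceiling) — is labeled B.

The bulk activity metric is the per-frame count of reconstructed
points in the upper half of the bottle (`upper_fraction` = 0.5,
configurable).

## Experiment summaries

Event start times are joined to the O₂ series by linear interpolation
(events outside the series span are an error) and densities attached through
the gas model, so summary densities are always consistent with the summary
pO₂ by construction.  Each run is summarized by the minimal pO₂ of first
activity (any stage ≥ B), first climbing (stage C), and first flight
(stage F); missing behaviors are reported absent, not zero.  Replicates of
one gas aggregate by minimum.  Two robustness choices, both defaults of the
pipeline driver and both overridable:

* **Recovery phase only.**  Events before the run's pO₂ minimum are excluded
  from the minima: the first seconds of the flush still contain ambient air
  and fully active flies, which are not evidence about recovery thresholds.
* **Onset corroboration.**  A reported first occurrence must be backed by at
  least 3 events of its category within 15 s.  Real onsets are collective —
  every fly in the bottle crosses the gate within seconds — while
  reconstruction artifacts (ghost points from epipolar coincidences between
  nearby flies) are sporadic.  This mirrors the role of manual vetting in a
  bench analysis.  `first_occurrence_table` itself defaults to the plain
  minimum.

## Numerical and validation notes

Default simulated problem size is 4 flies, 180 s at 30 fps (5400 frame
pairs) per run; the end-to-end parameter-recovery check uses 10 seeded He
runs and recovers the configured 0.93 kg/m³ flight gate with a median
absolute error well under 0.01 kg/m³ (the recovered value is biased
slightly high, as it must be: flight can only be observed after the gate is
crossed, and the hazard delay converts to ≈0.004 kg/m³/s near the gate).
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce runs bit-for-bit.
Stage agreement against simulator ground truth is evaluated on events whose
truth window is unambiguous (≥ 1 s and ≥ 80% single-label purity for
surface stages; ≥ 50% purity for airborne stages): windows straddling a gt
stage boundary have no well-defined expected label.

## Known limitations

* Greedy linking without a motion model swaps identities when flies cross
  within the search radius; the vetting layer discards the resulting
  chimeric segments instead of preventing them.
* Two flies lying in the plane of the two camera centers triangulate
  ambiguously (four sub-threshold candidates); one-to-one greedy selection
  keeps two, but which two can alternate frame to frame.  A third camera or
  temporally-aware matching would resolve this; both are out of scope.
* Thresholds are reported as raw minima (with corroboration), with no
  uncertainty quantification.
* The density gate in the simulator acts instantaneously; real flies
  presumably have a soft transition region, so recovered thresholds on real
  data would carry additional biological spread.
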