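# Methods

This package implements the analysis pipeline of a driving-simulator
protocol for comparing glaucoma patients with normally sighted
controls, together with a synthetic-cohort simulator that exercises
every stage of the pipeline without access to human data.  This note
documents the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## The experimental protocol being modelled

Participants steer (speed is automatic) along a 7534 m two-lane
highway for four 278 s sessions at 100 km/h, reached 17 s after the
start.  Session tasks: S1 none; S2 verbalise letters projected on the
screen; S3 evade nine static obstacles by moving to the left lane;
S4 letters and obstacles combined.  Vehicle kinematics, steering and
gaze are sampled at 60 Hz.  Per eye, a 24-2 automated-perimetry field
(54 locations, 6° grid, two blind-spot points at 15° temporal, ±3°)
with its mean deviation (MD) is an input.

## Course model

Longitudinal position is kinematic: a configurable monotone
acceleration profile on [0, 17 s] followed by constant 27.78 m/s.  The
printed obstacle schedule fixes the default profile's displacement at
cruise onset to 275 m (the first obstacle, 350 m, is met 2.7 s into
the cruise phase); a quadratic in time with speed continuous at the
cruise boundary satisfies both constraints.  No constant-acceleration
profile can: covering 275 m in 17 s while ending at 27.78 m/s is
incompatible with uniform acceleration, so the profile is deliberately
configurable and only cruise-phase arithmetic is used for validation.

Dead reckoning between printed obstacle (time, position) pairs at
exactly 100 km/h reproduces most adjacent pairs to within ±0.06 s but
not all: the spans 1171→1521 m, 3563→6095 m (which contains the 270°
curve) and 6395→7262 m disagree by 0.10–0.25 s.  We treat this as a
property of the printed schedule (speed presumably dipped slightly in
curves) and validate course arithmetic on the consistent pairs.

Letter schedules place 32 letters over 25 preprogrammed positions: the
first onset at 6 s, 4 s display, offset-to-onset gaps uniform on
[3, 6] s (onset-to-onset gaps of 3–6 s would overlap the 4 s display,
so the offset-to-onset reading is adopted), resampled in whole if the
last offset would overrun the session.  The default 25-position layout
is a 5 × 5 grid in visual angle whose extreme columns and rows match
the study's estimated eccentricities (−6.4° to +36.1° horizontally,
−2.9° to +16.8° vertically at the default eye point of (150, 350,
780) mm relative to the 1090 × 770 mm screen).  Columns bunch toward
the road region with one far-peripheral column at 36.1°, so that only
the rightmost letters fall outside the ~21° span of the integrated
field — matching the protocol's description of its stimuli.

## Integrated visual field

The integrated visual field (IVF) takes, at each location around
fixation, the best monocular sensitivity.  Locations are matched in
visual space after mirroring the left eye's grid.  The IVF keeps the
52 locations with |x| ≤ 21°: at the four blind-spot-mirrored points
(±15°, ±3°) only the fellow eye sees and its value is used; the nasal
27° columns (each seen by a single eye, with no fellow-eye
counterpart) are excluded.  This convention yields exactly 52 points
with 13 per quadrant; the source protocol does not state how it
treated these edge locations, so the convention is ours and is
documented rather than asserted.

Sensitivity loss is summarised per quadrant as the percentage of
points strictly below 25 dB — 13 points per IVF quadrant; for
monocular fields the denominator is that eye's non-blind-spot count in
the quadrant (14 nasal/12 temporal).  The better eye is the one with
the higher (less negative) MD, ties going to the right eye.  MD is
always an input, never computed: no normative database ships with the
package.

## Driving metrics

Steering and lateral position are lowpass filtered with 2nd-order
Butterworth filters applied forward–backward (`filtfilt`).  Zero-phase
filtering avoids lag that would smear event-locked windows; its
side-effect, a squared magnitude response, puts the gain at the cutoff
at 0.50 rather than 0.71, which is asserted by test.  Steering
activity (SA) is the mean absolute steering rate (central differences
at 60 Hz, 0.5 s trimmed at session edges to suppress filter
transients) of the 2 Hz-filtered signal (SA-high) or the
0.5 Hz-filtered signal (SA-low), computed inside and outside the
obstacle windows ([−150 m, +200 m] around each obstacle, overlaps
merged) in every session regardless of whether obstacles were present.
SDLP is the sample standard deviation (n−1) of lateral position over
non-obstacle sections.

LongDtO is the longitudinal distance from the obstacle at the moment
the vehicle commits to the left lane: the last upward crossing of the
road centre (1.8 m) within 150 m before the obstacle after which the
vehicle stays left of centre until the obstacle, linearly interpolated
between samples.  The "last committed crossing" rule is our
interpretation (drivers may weave); undefined avoidances are excluded
from means and counted.  LatDtO is |y| when passing the obstacle
centre.  A collision is lateral clearance strictly below 1.6 m at any
sample with longitudinal overlap, taking the car as 4.5 m and
obstacles as 1.8 m (bicycles, pairs of bicycles) or 4.5 m (cars) —
obstacle dimensions are not printed and are configurable.

## Letter scoring

A letter is detected if any voice event falls within [onset,
offset + 1 s]; reaction time (LRT) is voice minus onset.  Matching is
greedy one-to-one, earliest onset first; with 3–6 s gaps plus the 1 s
grace, windows cannot overlap, so the greedy match is exact.  Surplus
voice events are logged, not scored.  Session summaries pool S2 and
S4: misses summed, LRT averaged over all detected letters (pooled
rather than per-session-then-averaged; configurable).  The patient
correlation table is Spearman's ρ of each quadrant-loss percentage
(IVF, better eye, worse eye) against misses and LRT.

## Eye-scanning metrics

Preprocessing removes each maximal run of invalid samples plus 0.5 s
margins on both sides, drops surviving segments shorter than 1 s,
lowpass-filters each retained segment at 20 Hz, and reports the
removed fraction against full session duration.  A participant is
excluded from all eye analyses if any session exceeds 60 % removal.

Fixations use the dispersion-threshold algorithm (I-DT): a window of
at least 150 ms (the protocol's printed "150 m" is read as 150 ms —
physically forced) whose dispersion stays within 3° is grown sample by
sample and emitted at its centroid.  Dispersion is the classic x-extent
plus y-extent; millimetres convert to degrees through a small-angle
division by the viewing distance (default 780 mm, consistent with the
~70° horizontal field of view over the 1.09 m screen).  Each sample is
treated as covering one 1/60 s frame, so a minimal 9-sample window has
the full 150 ms duration.  Windows never span removed gaps.

Fixation rate divides by retained time, not session time (removed data
cannot contain detectable fixations); saccade amplitude is the mean
centroid-to-centroid distance of consecutive fixations within one
retained segment; dwell percentages use full-width top and bottom
bands of 20 % screen height by default (the protocol's exact
rectangles are not printed; both are configurable).

## Statistics

Group contrasts use Welch's t (Welch–Satterthwaite df), session
contrasts a paired t, associations Spearman's ρ with midrank ties and
a t-approximation p (exact permutation available for n ≤ 10).  All
tests are two-tailed at α = 0.05 with no multiplicity correction,
matching the protocol's explicitly argued choice for a small sample.
NASA-TLX totals rescale the six 1–21 item ratings to 0–100 %.
Standard routines (scipy.stats) compute the statistics; the test suite
verifies them against direct formula evaluations to 1e-10 and checks
the type-I error of the Welch test at the study's group sizes
(12 vs 23, variance ratio 2.5) over 5000 null replicates.

## Synthetic cohort

The generator's defaults are the study's conditions: 12 controls and
23 patients, patients recruited by scotoma pattern (one eye only ×2,
alternated hemifields, both upper, both lower; 4/6/5/5/3 — the printed
4/7/5/6/3 sums to the 25 recruited rather than the 23 analysed, so one
patient is trimmed from each of the two largest groups).  All
randomness derives from one seed via `SeedSequence` spawning — one
child per participant, one grandchild per data component — so skipping
a component never perturbs another.

**Visual fields.** Healthy sensitivity declines from ~31 dB by
0.08 dB/deg with 1.2 dB point noise.  Patients superimpose (a) the
recruitment pattern: the affected hemifield(s) depressed by a scotoma
depth ~N(25, 4) dB with per-point variability; and (b) bilateral
background loss: a random location subset, shared between the eyes and
drawn with independent severities per hemifield (uniform 0–55 % of
points, depth 35–85 % of the scotoma depth).  The shared-location
background is what makes damage binocular and hence visible in the IVF
(patients' mean IVF loss lands near 40 %, like the study's), while
independent upper/lower severities keep upper- and lower-field loss
decorrelated across patients — the structure behind the observed
upper-vs-lower correlation asymmetry.

**Driving.** Lateral dynamics are kinematic (yaw rate proportional to
steering-wheel angle through an 18:1 ratio and 2.7 m wheelbase;
lateral speed v·heading).  The driver is a proportional–derivative
tracker of a target lane position with closed-loop natural frequency
2.2 rad/s and damping 0.85, discretised zero-order-hold at 60 Hz and
evaluated through per-input transfer functions (`lfilter`), which is
exact for the linear loop.  The target is the right-lane centre plus a
slow attentional wander (0.4 m RMS below 0.04 Hz, per-participant
scaled), ramping to a 3.0–3.5 m plateau around each obstacle over a
~70 m ramp centred so the road-centre commit point falls 65–92 m
before the obstacle.  Steering noise has a slow band (≤0.3 Hz, control
RMS 1.4°) and a fast band (0.5–1.5 Hz, control RMS 0.3°).  Patients
apply 1.35× slow noise, 1.6× fast noise, 1.2× tracking gains and a
shorter (52 m) ramp: more steering activity at both cutoffs with
essentially unchanged SDLP, LongDtO and LatDtO — the study's pattern.
These defaults put a default control cohort near the study's control
means (SA-high ≈ 2.0 deg/s, SA-low ≈ 0.7 deg/s, SDLP ≈ 0.4 m, LongDtO
≈ 52 m, LatDtO ≈ 3.3 m).  A human driver is of course not a PD
controller; this is the simplest model in which steering activity and
lane keeping can be tuned independently.

**Letter responses.** Detection is evaluated with gaze fixed at the
focus of expansion: each letter's visual-field direction is looked up
at the nearest IVF location (letters beyond the ~21° margin use a
configurable 20 dB periphery floor), and the miss probability is
logistic in (threshold − sensitivity) with threshold 13 dB and slope
0.4/dB.  Detected letters respond at base RT + 0.010 s/deg ·
eccentricity + lognormal noise, truncated at the 5 s window.  Each
participant's base RT is 0.78 s plus 0.95 s per unit fraction of
depressed IVF points, which produces both the group LRT gap and the
within-patient loss–LRT correlation.

**Gaze.** Gaze dwells at the focus of expansion with slow
Ornstein–Uhlenbeck jitter (8 mm, τ = 1.5 s), glances at scene targets
(speedometer, rear-view mirror, side mirror, road scene; 0.22 visits/s,
0.35–0.75 s dwell), deviates to letters ~0.25 s after onset in the
letter sessions, blinks at 0.10–0.22 Hz (~0.15 s gaps) and loses
tracking in dropout segments.  A poor-tracking minority (probability
7/23 for patients, 1/12 for controls, matching the study's exclusion
tally) has heavy dropout that usually pushes a session past the 60 %
exclusion limit.  Defaults yield ~0.7 fixations/s, ~220 mm saccade
amplitudes and sub-1 % top/bottom dwell — the magnitudes the analysis
expects — with no built-in group difference.

**Workload.** TLX totals are drawn around group trends: controls
~26.5 % drifting down 1 %/session, patients starting ~18 % and rising
4 %/session, with 13 % between-subject spread — reproducing the
equal-means-but-opposite-trends pattern.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline computes each measure as
specified (closed forms, brute-force oracle equivalence), that the
statistics are calibrated, and that when data contain the study's
qualitative structure the pipeline recovers it (patient−control signs
for SA-low, misses and LRT in ≥90 % of 20 replicate cohorts;
upper-quadrant IVF loss correlating with misses more strongly than
lower-quadrant loss).  They do not validate the generator as a model
of human drivers: real steering is adaptive and nonstationary, real
scotomas are arcuate rather than random point sets, and real patients
partly compensate with eye movements.  In particular, because the
detection model deliberately keeps gaze at the focus of expansion,
deep-hemifield patients miss more letters (patient mean ≈ 12 per
pooled session pair) than the study's patients did (≈ 6) — the
direction and correlation structure, not the absolute miss count, are
the reproduction targets.

## Numerical choices and degenerate inputs

Filtering requires ≥ ~40 samples (filtfilt padding); shorter inputs
raise data errors.  SA masks within 0.5 s of session edges are
dropped.  Undefined values (no committed crossing, zero detections,
fewer than two same-segment fixations) propagate as None/NaN and are
excluded from means with counts, never silently zero-filled.  Ties:
better eye → OD; voice events on a window edge → detected (closed
interval); sensitivities exactly at 25 dB → not depressed (strict
inequality); collisions exactly at 1.6 m → not collisions (strict).
Problem sizes in the acceptance script (20 replicate cohorts, 5000
null t-tests, 200 oracle segments, 100 oracle traces) were chosen to
make the checks statistically meaningful while completing in about a
minute on one CPU.
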