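# Methods

`rok` is a headless re-implementation of a random-object kinematogram (ROK)
stimulus engine: a field of *oriented objects* ("oobs") that each carry a
movement direction **and** an orientation, animated inside an aperture.
Because the two features are controlled independently, the engine can vary
task difficulty (coherence of the task-relevant feature) and stimulus
interference (congruency of the task-irrelevant feature) on continuous
scales. Everything runs against a simulated frame clock — there is no
display, browser, or wall-clock dependency — and every random decision flows
through a caller-supplied `numpy` generator, so identical seeds give
bit-identical stimuli, frames, and trial records.

## Coordinate and unit conventions

Canvas coordinates are browser-style: origin top-left, x rightward, y
downward, lengths in float pixels. Angles are degrees, counter-clockwise on
screen, with 0° pointing right; 90° is therefore visually *up* (−y). The
screen-handedness of angles is a documented convention of this package, not
something the stimulus parameterization itself pins down. Sizes and speeds
default to *aperture-relative* units — percentages of the aperture width,
speeds per second — and are converted to pixels once, when a layer is
realized (`units = "px"` switches to absolute pixels). Aperture centers are
placed as percentages of the canvas width/height.

## Class assignment

Nominal proportions (coherence, opposite-coherence, congruency level) must
become exact integer counts of displayed objects. All partitions use
**largest-remainder apportionment**: quotas `n·p` are floored and the
remaining units go to the largest fractional remainders, with ties broken in
a fixed priority order (coherent > opposite > random; congruent >
incongruent). This guarantees counts sum to `n`, realized fractions sit
within `1/n` of nominal, and partitions are identical across runs.
Density-based object counts (`count × area / density_unit_area`) round half
away from zero, matching common canvas arithmetic. Class *membership* is a
seeded permutation of object indices, so different seeds permute members
while counts stay fixed.

### Congruency modes

In congruency mode the coherence parameter of the non-task feature is
reinterpreted as the **congruency level**: over the scoped object set, a
largest-remainder fraction of objects receives the coherent (target)
main-task direction on its secondary feature, and the remainder its 180°
opposite. Defining congruency relative to the *target* direction — rather
than each object's own realized direction — is what makes the reference
arithmetic exact: at a 75% level over 600 objects, exactly 450 carry the
target direction on the irrelevant feature regardless of the main task's
coherence. Two scopes are exposed because the parameter documentation and
the experiments describe different object sets:

- `coherent_only` (default): the split applies only to coherent main-task
  objects — for these the target direction and the object's own direction
  coincide, so both readings agree;
- `all_objects` (used by the experiment builders): the split covers the
  whole layer, reproducing the 450-of-600 bookkeeping.

Out-of-scope objects get a uniform-random secondary feature
(`random_rest`) or copy their own main-task direction (`yoked_rest`). A
yoked copy of a *random* main direction keeps that realized angle; if the
secondary feature is also declared time-varying it will be re-randomized on
subsequent frames — the experiment fixtures use fixed random types, where
this edge case never arises.

## Kinematics

Each frame advances objects by `speed · dt` along their direction, with
`dt = 1/fps` (default 60 fps). Per-object speeds are drawn once, uniformly
on `[base(1−r), base(1+r)]` for randomisation fraction `r` (r = 0 gives the
exact base speed). Random-class features are either fixed for the trial or
re-drawn uniformly on [0, 360) every frame (`time_varying`); every frame
with a full redraw is the simplest defensible cadence and is the one
implemented.

**Boundary rule.** An object that leaves its aperture re-enters at a
uniformly random *admissible* boundary point — one whose inward normal has a
positive component along the object's heading — with direction, class,
speed, and orientation preserved. This opposite-locus reinsertion is
standard kinematogram practice: it conserves class counts and coherent
motion energy, and introduces no directional drift. For rectangles entry
points are uniform in perimeter length over the admissible edges; for
ellipses they are uniform in the ellipse's angular parameter (not arc
length), a deliberate simplification since elliptic apertures are not used
by the reference designs.

**Edge fade.** With `fade_out` on, opacity ramps linearly from 1 to 0
across the outer 10% of the aperture's normalized boundary distance
(per-axis half-extent scaling for rectangles, radial for ellipses); the
band width is a fixed, documented choice.

**Frame clock.** The clock is headless: kinematics always use the nominal
dt, while the recorded per-frame millisecond durations can be jittered with
seeded Gaussian noise to emulate browser timing variance in the trial
record's frame-rate bookkeeping. Jitter never feeds back into object
motion.

## Rendering

Frames composite the background (solid color or image), then each
(aperture, layer) pair in order — optionally seeded-shuffled — with each object
drawn at its position, its alpha, and clipped to its aperture mask.
Triangles are isosceles with height = object size and base = 0.6 × height,
centered on their centroid with the apex along the orientation (the original
triangle is shown but never parameterized; the ratio is fixed here for
reproducibility). Squares rotate with orientation; circles are
orientation-invariant. Sprites rotate about the center of their bounding
box, or, when a mirror axis is set, are reflected across that axis instead
of rotated (vertical-axis mirror when the orientation points left,
horizontal-axis when it points down). Keyframed sprites cycle as
`floor(t / keyframe_time) mod n_keyframes`. Anti-aliasing is off so rasters
are bit-exact reproducible. The bird and leaf sprites and the "nature"
background are small procedurally generated synthetic stand-ins for artwork
this package does not ship.

## Trials

`run_trial` drives a responder callback against a trial spec: fixation,
then up to `trial_duration` ms of stimulus (0 = endless loop). Invalid keys
are ignored; a valid response after the deadline counts as a timeout. RT is
continuous milliseconds from stimulus onset — not snapped to frame
boundaries — and the number of displayed frames is `floor(rt · fps/1000)`
(minimum 1); a response before the second frame yields a recorded frame
rate of 0 Hz. Feedback labels follow the training/experimental convention:
`TOO SLOW` on timeouts, `FALSE` on errors, `CORRECT` only for accurate
training responses, nothing for accurate experimental responses. Because
object kinematics are seed-deterministic and independent of the response
channel, `run_trial` evolves the object field only when a trajectory log is
requested; the frame clock and the data record are identical either way.

## Experiment fixtures

`build_experiment` constructs the complete reference designs with no
external data: 16 training trials, then ten 72-trial blocks. Factorial
blocks (2–5, 7–10) cross coherence {90, 75, 60}% with congruency
{100, 75, 25, 0}%, six repetitions per cell, seeded-shuffled; the judged
feature switches between halves and task order / key mapping are
counterbalance options. Displays are two-directional (opposite-coherence
= 1 − coherence; target up or down at random per trial). Distractor blocks
(1, 6) fix coherence at 65% and congruency at 50% and add a second
70-object layer — squares, points, or randomly oriented triangles, each
object turquoise or yellow with equal probability — on a per-trial
Bernoulli(0.10) draw ("drawn randomly" admits either reading; a fixed
7-of-72 quota mode is provided as an option). Target layers use 600
objects at 1% size and 3%/s speed; the aperture is a 600×600 px rectangle
on an 800×600 canvas (fixture defaults — the reference displays never
print aperture geometry).

The **synthetic observer** is a testing instrument: accuracy is a
lapse-mixed logistic in coherence and congruency, RT a shifted log-normal
whose location falls with both. Defaults (intercept −2.95, coherence slope
5.95, congruency slope 1.11 on the log-odds of a correct response; lapse
0.02; RT shift 300 ms, log-location 7.0 − 0.72·coherence −
0.10·congruency, log-scale 0.25) place error rates between roughly 3% (easy
cells) and 35% (hard cells) and RT effects of a few hundred ms — the
qualitative psychometric regime the engine is meant to exercise. They are
illustrative, not fitted to any dataset; passing recovery tests show the
pipeline preserves directional effects, not that these numbers describe
human observers.

`filter_trials` annotates (never deletes): fast responses (< 200 ms),
timeouts (no response within 2000 ms), errors, post-error trials (for RT
analyses), and a participant-level exclusion flag at ≤ 60% accuracy on
experimental trials.

## Diagnostics

`audit_log` is the engine's independent audit: it ignores logged class
labels and directions, re-deriving movement from displacement finite
differences. Reinsertion frames are detected as jumps exceeding 3× the
object's median per-frame displacement and excluded. Each object is then
classified by the majority direction of its kept steps against the coherent
direction (angular tolerance 1°, which only absorbs float error since
classes are exact angles by construction) — majority classification is what
makes coherence/opposite/congruency counts recover *exactly* despite
excluded frames. Mean speed is the mean kept displacement per second,
reported as % of aperture width. With uniform random movers present, a
tolerance band unavoidably captures ≈ 2·tol/360 of them by chance; exact
1/n recovery statements therefore apply to exact-angle (two-direction)
displays, the configuration the reference experiments use.
`frame_rate_histogram` bins per-participant mean frame rates, excluding
0 Hz trials.

## Problem sizes and limitations

Tests and the acceptance script use the study-scale configurations (600
objects, 120 frames at 60 fps, ≥ 10⁴ design trials for rate estimates)
since they run in seconds. What the synthetic data cannot show: browser
timing artifacts beyond Gaussian jitter, perceptual/motor variability
richer than the observer's three-parameter psychometric, pixel-level
motion energy (the trajectory log, not the raster, is the audited ground
truth), and any claim about human behavior. The original plugin's exact
reinsertion rule, time-varying cadence, and RT quantization are not
publicly specified; the conventions above are this package's documented
choices.
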