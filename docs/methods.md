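# Methods

This note documents the models, parameter choices and numerical
conventions behind `zapgaze`, and what the synthetic benchmark does and
does not establish about real recordings.

## The task being emulated

The generator reproduces the structure of a continuous face-targeting
("zapping") experiment: a 31° × 22° display (2560 × 1440 px), 3°-tall
face targets, monocular gaze sampled at 1250 Hz in degrees of visual
angle (origin at screen center, x rightward, y upward). A trial ends when
gaze has stayed inside the 3° × 3° window centered on the face for 2
consecutive samples (1.6 ms); the next trial's stimulus appears after the
tracker's ~5 ms transmission delay plus a screen update drawn from
N(18, 1.5²) ms (median 18 ms). Sessions are blocks of 500 trials in one
of four conditions (scene/no-scene × upright/inverted); block order is
counterbalanced by choosing one of the 4! = 24 condition permutations per
subject. Two placement schemes are supported: uniform over the screen
with the whole target window on-screen (`full_screen`), or exactly 4°
from the previous target at a polar angle uniform over the sectors
[0°, 45°], [135°, 235°], [315°, 360°] (`step4deg`), resampled until
on-screen (capped, then an error).

## Movement model

**Main sequence.** Peak velocity follows the saturating law
V_peak = V_max·(1 − e^(−A/C)) with defaults V_max = 750 °/s, C = 8°,
chosen so that a 10° saccade peaks near 535 °/s and sub-degree
microsaccades near 30–80 °/s, as in high-speed recordings.

**Waveform.** Each movement has a raised-cosine velocity profile,
v(t) = V_peak/2 · (1 − cos 2πt/D), integrated in closed form so that the
displacement equals the commanded amplitude exactly. A raised cosine
fixes the duration once amplitude and peak velocity are set:
D = 2A/V_peak. We adopt that constraint rather than an independent
duration rule (the common A-linear rule D ≈ 2.2A + 21 ms cannot coexist
with an exact amplitude and a main-sequence peak under this profile);
for amplitudes up to ~10° the two agree within a few ms anyway.

**Targeting.** Saccade latency is Gamma-distributed (mean 150 ms, SD
30 ms — literature-typical; the task description does not state one).
Endpoints scatter around a weighted-random facial landmark with Gaussian
jitter (SD 0.25°), truncated to the target window for "hit" saccades; a
configurable fraction (default 84%) of first saccades lands in-window.
Misses land 2.2–3.8° from the face center and are followed by a
corrective saccade after a fresh latency.

**Post-saccadic microsaccades.** After the saccade that completes a
trial, with probability p (default 0.2) a single microsaccade is planned
with launch latency uniform over 1–25 ms after the saccade offset
(snapped to the sample clock). Its endpoint is drawn from a
landmark-anchored mixture whose weights depend on face orientation
(upright → eyes/forehead-weighted, inverted → nose/chin-weighted), with
amplitude clamped to 0.60–0.90°; its direction differs from the preceding
saccade's polar angle by more than 45° with configurable probability
(default 84%), enforced by rejection sampling within the mixture with an
explicit angular-construction fallback. A planned microsaccade is
*suppressed* if the next stimulus onset precedes its launch — the
stimulus change cancels the pending plan. This choice is what makes the
interval between trial onset and the first saccade essentially
microsaccade-free, the task's signature temporal structure; it also means
the realized per-trial microsaccade probability is p times a survival
factor slightly below 1 (exactly 29/30 when the update jitter is zero).

The amplitude floor of 0.60° deserves a comment: at 1250 Hz with 0.02°
sensor noise, the λ = 5 median-based threshold lands near 30–35 °/s
(inflated above the pure-noise value because this task keeps the eye in
motion a large fraction of the time), and movements below ~0.5–0.6° do
not stay above it for the required 10 samples. The microsaccade
population the analysis pipeline defines is the *detected* population, so
the generator draws amplitudes that the defining criterion can detect.
Real recordings surely contain smaller microsaccades; this benchmark says
nothing about them.

**Inverted faces** are modeled as a 180° rotation of the upright landmark
layout (not a mirror flip). Landmark labels stay attached to the same
physical features, so the correspondence between any trial's landmarks
and the upright template remains a proper rotation — consistent with the
reflection-free Procrustes fit. Per-trial landmark variability is
Gaussian jitter (SD 0.05°, clipped to the face box) plus small scale
(±6%) and rotation (±5°) perturbations, which leaves a realistic nonzero
Procrustes residual (~0.057° RMS).

**Noise.** White Gaussian per-sample position noise (default SD 0.02°)
is added to the whole trace; an optional random-walk drift is off by
default. Blinks, pupil dynamics and binocular disparity are not modeled.

## Detection

Velocity is estimated with the standard 5-sample difference filter
v_n = (p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2})/(6Δt); the two samples at
each edge carry zero velocity and are excluded everywhere. The per-axis
threshold is η = λ·σ with σ = √(median(v²) − median(v)²) (λ = 5); for
Gaussian noise σ converges to 0.6745 × SD, the square root of the median
of a χ²₁ variable. Thresholds are estimated per continuous recording
segment (per block) — trials are far too short for stable medians.
Events are maximal runs of samples outside the elliptic threshold
(v_x/η_x)² + (v_y/η_y)² > 1; runs separated by ≤ 2 sub-threshold samples
are merged before the ≥ 10-sample duration test (the merge gap is
configurable and logged; a value of 0 disables merging).

Magnitude is the component-wise max−min extent over the event
(the toolbox convention), with onset-to-offset displacement available via
`magnitude_definition="displacement"`; events below 1° are microsaccades.
Peak velocity is the maximum sample speed in the event (earliest sample
wins ties); polar angle is the onset→offset direction in [0°, 360°).

Because the threshold sits ~5 noise SDs above zero, raw threshold
crossings systematically lag movement onset by a few samples. By default
the detector therefore extends each event's bounds outward to the nearest
local minimum of normalized speed (capped, and never into a neighboring
event). This refinement is a separate step from run extraction — the core
run logic is exactly the boolean-run procedure above — and brings the
median onset error on simulations to about one sample.

Degenerate inputs raise informative errors: fewer than 5 samples (no
velocity), fewer than 10 interior samples or a zero noise estimate (no
threshold), a single event (no main-sequence fit), collinear landmarks
(no Procrustes fit), singular endpoint covariance (no Gaussian fit; the
message suggests jitter).

## Analyses

Peri-event alignment attributes *every* event inside the window around a
trial's anchor to that trial, mirroring how rasters are built from a
continuous recording (neighboring trials' saccades appear at the window
edges). Occurrence histograms report the percentage of trials with at
least one event onset per bin (default 4 ms bins; the figure-style
binning is not dictated by the data, so it is configurable). Per-subject
rates divide onset counts in the (−200, 800) ms interval by
trials × interval length; the across-subject CI is a two-sided
t-interval. The saccade→microsaccade association window after saccade
offset defaults to 100 ms; angular congruence wraps differences to
[0°, 180°] and splits at 45°. Eccentricity profiles use 2°-wide bins from
4° to 20° by default, with empty bins reported. Trials whose first
saccade cannot be resolved are excluded from anchored analyses and
counted in QC; for the "correct" run criterion they count as incorrect.
Run tables count only maximal runs and do not let streaks span block
boundaries (a recalibration pause breaks a streak; `span_blocks=True`
overrides).

The heatmap grid pitch is 22°/1440 px ≈ 0.01528°/px, so the 5 × 5-pixel
disk kernel (13 cells of weight 1/13) subtends ≈ 0.076°. Smoothing uses
zero padding; the mass lost over the grid boundary is computed and
reported rather than silently renormalized. Map similarity is cosine
correlation (so disjoint point maps score exactly 0) plus the
total-variation distance between unit-mass maps.

## What the benchmark shows — and what it does not

Passing tests establish that the pipeline is *self-consistent*: the
detector recovers the generator's events (recall/precision ≥ 0.95 for
saccades ≥ 2°, ≥ 0.90 for microsaccades at default noise), the analysis
stack recovers the generator's parameters (microsaccade probability,
direction incongruence, targeting accuracy) within binomial confidence
intervals, and the qualitative structure — no pre-saccadic microsaccades,
orientation-dependent landing maps — follows from the generative model by
construction. The generator's white, stationary noise, its single
post-saccadic microsaccade per trial, its absence of blinks, drift,
overshoot dynamics and head motion all make detection *easier* than on
real recordings; results on real data will be correspondingly noisier,
and the parameter defaults that the task description does not pin down
(latency distribution, endpoint scatter, noise level) are
literature-typical placeholders, not estimates.

## Problem sizes

The test suite and acceptance script use sessions of 200–2,000 trials
(one to four blocks) — large enough for binomial CIs at the 1–20% rates
of interest and for every 2° eccentricity bin to hold ≥ 50 trials, while
a full run stays within a few minutes on one core. The full published
design (24 subjects × 8 blocks × 500 trials = 96,000 trials per
experiment) is the generator's default configuration and is checked
arithmetically.
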