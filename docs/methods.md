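# Methods

This note documents the models, conventions and numerical choices behind
`mindseye`, in the order the pipeline applies them.

## Screen geometry and visual angle

All analyses work in screen pixels (origin top-left, y downward, times in
ms). Conversions between visual angle and on-screen extent use the exact
chord formula `extent = 2 d tan(theta / 2) / pitch`, where `d` is the
viewing distance and the pixel pitch is fixed by a calibration pair — an
angle and the pixel extent it is known to subtend on the recording setup.
The default geometry (1920 x 1080 at 855 mm, 5 degrees = 270 px) gives
135 px for 2.5 degrees, the recurrence radius used throughout. We do not
use a small-angle linear approximation: at 7 degrees the chord conversion
gives 378 px where a linear scale gives 378 as well but both drift from a
hardware-reported 377 px by one pixel; rounding is half-up and the
conversion is defined, not fitted. `px_to_deg` inverts the unrounded
conversion exactly.

## Fixation filtering

Fixations are dropped when off-screen or with durations outside
[100, 5000] ms. The duration cut-offs are strict inequalities (exactly
100 ms or 5000 ms is kept) because the rule is phrased as "shorter
than"/"longer than"; the screen is the half-open rectangle
[0, width) x [0, height), so a coordinate exactly at the width is
off-screen. Removal reasons are assigned with precedence off-screen →
too short → too long, making the per-reason counts a partition of the
removed set. Filtering is idempotent. QC summaries z-score per-participant
totals across participants and only flag (default |z| > 3); they never
exclude.

## Event detection

The detector re-implements the standard velocity/acceleration principle:
a sample is fixational iff the pupil is valid and gaze velocity and
acceleration magnitude are strictly below 30 deg/s and 8000 deg/s^2.
Positions are converted to visual angle about the screen centre, smoothed
with a centered moving average (default 5 samples), differentiated by
central differences (one-sided at the track edges), and maximal
fixational runs of at least 40 ms become fixations (position = centroid
of the run's raw samples, duration = run length x sampling interval).
Because the comparison is strict, a velocity sitting numerically on the
threshold is treated as saccadic; a relative guard of 1e-9 absorbs
floating-point error in that comparison. Tracks must be uniformly sampled
to within 10% jitter. Hardware parsers apply proprietary smoothing, so
onsets are only guaranteed to match a known ground truth to within one
smoothing window; blink (invalid) samples always break runs.

## Quadrant AOIs and the looking-at-nothing slope

The screen is split into four equal quadrants (half-open cells: midline
points go right/down). Each trial yields a 4-vector of fixation
proportions per phase. The looking-at-nothing association is the pooled
least-squares slope of imagery proportions on encoding proportions over
all (trial x quadrant) points. Under a replay-with-mixing model —
imagery = lambda x encoding + (1 - lambda) x uniform — the slope equals
lambda in closed form, which the tests verify; a positive slope is the
LAN signature. We deliberately use this descriptive pooled regression
rather than a hierarchical zero-one-inflated beta model: it is
dependency-free, exactly reproducible, and preserves the sign and
magnitude structure of the coupling; it does not provide shrinkage or
credible intervals.

## Scanpath similarity

Scanpaths are turned into saccade-vector sequences, optionally simplified,
aligned, and scored on five dimensions. Simplification merges a pair of
consecutive saccades when the intervening fixation is briefer than 300 ms
and either both amplitudes are below 10% of the screen diagonal or the
directions differ by less than 45 degrees; merged vectors sum and the
intervening duration is pooled into the originating fixation. The
parameters are the common defaults of the vector-alignment family of
scanpath measures and are exposed in `SimilarityConfig`. Alignment is a
dynamic program over the matrix of vector-difference magnitudes (monotone
steps right/down/diagonal, diagonal preferred on ties). Dissimilarities
per aligned pair are normalized to [0, 1] — vector difference over twice
the diagonal (shape), amplitude difference over the diagonal (length),
angular difference over pi (direction), endpoint distance over the
diagonal (position), duration difference over the pair maximum
(duration) — averaged with the mean (configurable nowhere else because
the choice between mean and median is not settled in the literature; the
mean is the common default) and flipped to similarities. Angular
differences are computed with atan2 so identical vectors score exactly 1.

## Recurrence quantification

Two fixations are recurrent when their Euclidean distance is at most the
radius (inclusive; default 2.5 degrees → 135 px at the default
geometry). With `R` the recurrent pairs in the strict upper triangle of
the n x n recurrence matrix:

- recurrence rate = `100 * 2R / (n (n-1))`,
- determinism (DET) = percentage of upper-triangle recurrence points on
  diagonal runs of length >= 2,
- laminarity (LAM) = `100 (H + V) / (2R)` with `V` the upper-triangle
  points on vertical runs and `H` those on horizontal runs.

Printed formulas in the literature leave three things open, which we pin
and oracle-test: (1) runs are scanned along full rows/columns and the
self-recurrence diagonal joins runs (distance zero is genuine
recurrence) but its points are never counted; (2) all counts are taken in
one triangle, with LAM's `2R` denominator representing both; (3) when
there is no recurrence at all, DET and LAM are 0 and the result carries a
`degenerate` flag. One consequence worth knowing: for a scanpath of n
identical fixations DET is `100 (R-1)/R`, not exactly 100 — the single
recurrence point on the length-1 corner diagonal cannot sit on a run of
two — while LAM is exactly 100 because the self-recurrence diagonal
bridges every column run. The fixation-spread covariate is the RMS
distance of fixations from their centroid (definition chosen here; used
because concentrated gaze inflates every recurrence measure trivially).

## Synthetic cohorts

The generator is anchor-based: a trial owns `n_anchors` attractor points
(minimum 200 px apart, 100 px from the edges), and a scanpath is a walk
whose three levers map one-to-one onto the recurrence measures —
`revisit_prob` → recurrence, `order_fidelity` (revisits follow the
successor in the first-tour order) → determinism, `cluster_dwell`
(consecutive fixations per visit, 1 + Poisson) → laminarity. Mode presets
encode the four regimes: free (0.30 / 0.20 / 1), part_based
(0.55 / 0.90 / 3: a gaze-contingent window forces sequential part-by-part
tours), holistic (dispersed >= 500 px jumps, no revisit structure: an
artificial scotoma suppresses central scrutiny), imagery
(0.75 / 0.90 / 2). Preset values are the package's own choices, picked to
caricature the regimes at realistic effect sizes, not fitted to any data.
Durations are log-normal (median 220 ms, sigma 0.35) clipped to
[100, 5000] ms; positions get Gaussian jitter (default 15 px) and 25-45 ms
inter-fixation gaps.

Within a cohort, imagery is coupled to its own encoding: each encoding
fixation's anchor token is kept with probability lambda
(`encoding_coupling`, default 0.7) or replaced by a uniform random screen
position, and kept tokens are re-ordered into repeated first-tour sweeps
with dwell runs. Because the kept multiset is preserved, lambda = 1 with
zero jitter makes the imagery position multiset exactly the encoding one:
AOI profiles coincide per trial and the LAN slope is exactly 1. Two
modelled limitations follow. First, recurrence rate depends only on the
position multiset, so coupled imagery can never exceed its encoding's
recurrence (equal at lambda = 1, diluted below it otherwise); the
imagery-versus-free recurrence direction seen in human data is carried by
the imagery *preset*, not by the coupled phase. Second, free viewing has
single-fixation visits, so its laminarity is exactly 0 — real free
viewing has occasional dwells. More generally the generator has no
stimulus images, no salience, no centre bias and no fatigue; passing
directional tests shows the measures respond to the constructs they
target, not that human effect sizes are reproduced.

Raw-track rendering places samples at the fixation position plus
Gaussian noise (default 0.02 degrees, quiet-tracker RMS) for the
fixation's duration and ramps linearly across inter-fixation gaps, giving
saccade velocities far above threshold; blink gaps mark samples invalid.
Everything streams from one master seed through per-trial `SeedSequence`
substreams keyed by (seed, participant, trial), so enlarging a cohort
never changes existing trials.

## Contrasts and calibration

Condition contrasts are differences of participant-level condition means
with a percentile bootstrap over participants (clusters), paired when
every participant has both conditions. Under a simulated null the 95%
intervals exclude zero in about 5-7% of replicates (percentile intervals
are mildly anti-conservative at n = 50); the calibration test enforces
5 +/- 2 percentage points. Bootstrap draws are reproducible bit-for-bit
from (seed, n_boot).

## Problem sizes

Default tests and the acceptance script use 40-fixation trials, 200
trials per regime arm, 500-scanpath oracle sweeps, and 400-500 null
replicates with 1000-2000 bootstrap draws — sizes chosen so the whole
battery runs on a laptop in well under a minute per component while
keeping Monte-Carlo error far below the tested margins.
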