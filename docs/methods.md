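# Methods

## Stimulus model

Each trial shows 12 items — two copies of each of 6 item types drawn from
the 3 colors × 3 shapes taxonomy — moving inside a 26° × 20° arena (degrees
of visual angle, origin at screen center, x right, y up) for 3 s at 60 Hz
(180 frames). Item size is 1.52°; items are placed uniformly at random with
pairwise center distance ≥ one item size (rejection sampling, capped at
10,000 attempts, failure raises `ArenaTooSmallError`).

Composition sampling is uniform without replacement: prime-present trials
force the prime in and draw 5 of the remaining 8 types (56 equally likely
displays); prime-absent trials draw 6 of 8 (28 displays). The full 6-of-9
space has 84 members. No "shares a feature with the prime" filter is needed:
of the 8 non-prime types, 4 share a feature, so by pigeonhole every
prime-absent display contains at least 2 sharers (asserted by enumeration).

The motion law is the simplest process consistent with "fixed speed,
pseudorandom": constant-speed linear motion with uniform initial headings
and specular reflection at the walls; items may overlap in flight. Speed is
a free parameter, default **5 °/s** — fast enough to demand tracking,
slow enough that smooth pursuit stays well under the parser's velocity
threshold. With zero heading jitter the reflected path has a closed form
(the unreflected coordinate folded into the arena as a triangle wave),
which the implementation uses; a per-frame heading-jitter option falls back
to the stepwise integrator. Speed is conserved across bounces; the chord
between reflected frame endpoints can only shorten on a bounce frame.

## Gaze model (synthetic observers)

There is no public gaze dataset for this paradigm, so observers are
simulated by the minimal process embodying the analysis's own assumptions:
gaze is a sequence of attentional episodes on single items, separated by
ballistic saccades. Per episode:

* **Target choice** — multinomial over the 11 non-current items with weight
  `w_c` for an item of match category *c* against the prime
  (`w_full, w_color, w_shape, w_none`, all default 1). Equal weights are
  the null model: the stationary distribution over items is uniform, so
  expected dwell proportions equal the trial's chance levels. Raising
  `w_full` plants a priming effect of controllable size.
* **Duration** — gamma with mean `fix_dur_mean` = 400 ms and shape
  `fix_dur_shape` = 6, truncated at ≥ 100 ms so every episode spans ≥ 6
  frames and is parseable. With 30 ms saccades this yields ≈ 7 episodes
  per 3-s trial, matching typical free-viewing fixation counts.
* **Tracking** — gaze follows `pursuit_gain · item(t) + (1 − gain) ·
  item(t_on)`: gain 1 is perfect pursuit, gain 0 a static fixation at the
  item's onset position. Default 0.8.
* **Noise** — two scales, mirroring how trackers are specified: a
  per-episode accuracy offset (sd `noise_sd` = 0.35°, mid-range of typical
  video-tracker accuracy) and per-sample precision jitter (sd `jitter_sd`
  = 0.01° RMS). Accuracy error is slowly varying in real recordings; white
  noise at the accuracy scale would produce velocity noise two orders of
  magnitude above any plausible saccade threshold and make event parsing
  meaningless, so it is modelled as an episode-constant offset.

The first episode targets screen center with probability `p_center_first`
(default 0.9), reproducing the generic center-of-screen first fixation of
free viewing; it makes first-fixation effects weaker than later ranks, as
the order-of-fixation analysis expects. Saccades last `saccade_dur` = 30 ms
with linearly interpolated positions. A terminal stub shorter than 100 ms
is avoided by extending the previous episode to the end of the trial. A
`p_invalid` option drops samples at random to exercise exclusion rules.

What the generator does **not** emulate: saccadic main-sequence dynamics,
blinks, drift/microsaccades within fixations, binocular disparity, or any
dependence of episode duration on item identity. Passing tests therefore
show that the pipeline recovers the biases this process plants — not that
human data would be this clean.

## Event parsing

A velocity-threshold (I-VT) parser stands in for the tracker's online
parser: central-difference speed (one-sided at the ends, NaN through
invalid samples), smoothed by a 5-sample moving average; maximal
sub-threshold runs become fixations. Defaults: threshold 30 °/s, minimum
duration 50 ms, merge gap 20 ms (sub-threshold runs separated by shorter
gaps are bridged — noise blips and brief dropouts). Smooth pursuit of
items at the default 5 °/s stays below threshold and is classified as
fixation, intentionally: tracking a moving item is attending it. Every
fixation's duration exceeds one display frame, so a frame holds at most
one fixation.

## Assignment and chance

Frame windows are half-open, [f/60, (f+1)/60) s; edge times are computed
as `f · 1000 / 60` (multiply before divide) so exact-millisecond
boundaries are exact in floating point. At 1000 Hz every window holds 16
or 17 samples; the analysis keeps the first valid one per frame. The
fixation basis instead uses, per frame, the fixation active at the frame's
onset, with its overall centroid as the gaze point — re-compared to the
moving item positions on every frame. Nearest item is the argmin of
Euclidean distance to item centers, ties to the lowest item id. Trials
with zero classifiable frames (or zero fixations, on the fixation basis)
are flagged excluded and never enter subject means.

The category of the *n*th fixation over moving items is ambiguous when the
nearest item changes mid-fixation; it is resolved by per-frame majority
vote over items, ties to the earliest frame's item, which reduces to the
obvious answer when the nearest item never changes. A trial enters the
per-rank analysis only with ≥ 4 fixations.

Per-trial chance is the item-count fraction per category (multiples of
2/12). `expected_chance` averages it over the exhaustive enumeration of
compositions in exact rational arithmetic and reproduces the closed forms
(1/6, 5/24, 5/24, 5/12) and (0, 1/4, 1/4, 1/2).

## Statistics

Subject means (over non-excluded trials) of observed and chance
proportions are both arcsine-transformed — arcsin √p, the standard
variance stabiliser for count proportions; both vectors are transformed
for symmetry — and compared by a paired t-test, two-sided, df = n − 1,
with paired Cohen's d = mean(diff)/sd(diff). Chance is treated as a
second sample rather than a constant because it varies with the drawn
composition. Zero-variance differences are flagged (t = 0, p = 1 when all
differences vanish; ±∞ otherwise). Reported means are untransformed. No
multiple-testing correction is applied; consumers comparing many
categories/ranks should account for that themselves.

## Determinism and problem sizes

A master seed plus (subject, trial) indices feed a `numpy.SeedSequence`,
so any trial regenerates in isolation and identical configs give
byte-identical output files. The calibration suites run at deliberately
reduced designs — the type-I calibration uses 500 replicates of 6 subjects
× 60 trials (pooled prime-present rejection rate ≈ 5%), bias recovery 50
replicates of the full 12 × 180 design, the parser round trip 500 single
trials — sizes chosen to give tight Monte-Carlo error while keeping the
whole suite a desk-scale run.

## Known limitations

* The generative gaze model is a caricature; parameters (`pursuit_gain`,
  episode durations, center-first probability) are exposed rather than
  fitted to any dataset.
* Nearest-center assignment ignores item boundaries; misassignment near
  item crossings degrades, but cannot fabricate, a priming signal.
* The fixation-basis gaze point is the fixation's overall centroid; using
  instantaneous within-fixation samples would differ slightly during
  pursuit-like episodes.
* Human effect sizes are not reproduced — only the machinery that would
  measure them, validated on synthetic observers with known ground truth.
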