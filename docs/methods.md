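# Methods

`embryokin` quantifies stimulus-evoked movement of chicken embryos in ovo
from markerless pose-estimation output. This note documents the model and
procedure the package implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## The measurement model

The input is a pose track: for each video frame (50 frames/s) and each
tracked body part, an x and y pixel coordinate plus a likelihood in
[0, 1] — the pose estimator's confidence that the landmark was located
correctly. Coordinates follow the image convention (y grows downward);
every quantity computed from them is invariant to that choice.

Body parts enter the analysis through *roles*, not raw label names: upper
and lower beak tips, the beak fulcrum, the medial eye corner, the elbow,
and a leg landmark — the metatarsus from embryonic day (ED) 12 on, but the
tarsus at ED9, where the metatarsal tissue is translucent and tracks
unreliably (the binding layer enforces this substitution). At least one
stationary point on the egg or instrument serves as a negative control:
its movement series should be indistinguishable from tracking noise.

## Quality control

Two masking steps precede all kinematics:

1. **Likelihood cutoff** (default 0.75). A frame with confidence strictly
   below the cutoff becomes missing; a frame at exactly the cutoff is
   retained (the boundary is not specified anywhere authoritative; we pin
   "mask when likelihood < cutoff" and test it). Masking is monotone in
   the cutoff because the likelihood values themselves are never edited.
2. **Outlier exclusion.** Tracking occasionally "teleports" a label across
   the image for a frame while reporting high confidence. The package
   screens each label's x–y cluster reproducibly: a frame is flagged when
   its per-axis scaled-MAD-standardized distance from the label's spatial
   median exceeds `k` (default 6) **and** the displacements into and out
   of that frame both exceed `k` times the robust scale of the label's
   frame-to-frame displacements. The second condition is what separates
   tracking artifacts from genuine behavior: a real beak opening can carry
   the beak tips tens of robust SDs from the resting cluster, but it gets
   there smoothly, a few tenths of a pixel per frame, whereas a tracking
   failure jumps there and back in single frames. A distance-only screen
   at any workable `k` would flag (and eventually exclude) exactly the
   post-stimulus intervals the analysis exists to measure. Labels whose
   MAD is zero on both axes (pinned reference points) are never flagged.
   Flags are advisory: they are produced, reviewable, and applied in a
   separate idempotent step, and a manual exclusion list can replace the
   automatic screen entirely.

## Kinematic parameters

Three per-frame parameters, missing whenever any required landmark is
missing that frame:

- **Beak distance** (px): Euclidean gap between the beak tips,
  `d = sqrt((xu − xl)² + (yu − yl)²)`.
- **Beak angle** (deg): unsigned angle at the fulcrum P0 between rays
  P0→P1 (upper tip) and P0→P2 (lower tip), computed from the unit vectors
  as `atan2(|det[n2 n1]|, n2·n1)` and converted to degrees; the absolute
  determinant makes it orientation-free, so it lies in [0, 180]. If a tip
  coincides with the fulcrum the angle is undefined and emitted as
  missing — substituting 0 would bias interval sums downward.
- **Movement** (px): displacement of one landmark between strictly
  consecutive frames; entry *t* spans frames *t* and *t + 1*, so the
  series has one fewer entry than the recording. Displacement is never
  computed across a masked gap (skipping frames would turn one dropout
  into a spuriously large jump).

Distance and movement are computed as the literal square-root of summed
squared differences (not `hypot`) so results are bit-identical to a
scalar recomputation of the same formula — exactness the test suite
asserts.

## Windowing and interval statistics

Each trial contains one noxious pinch and one light-touch control, in
randomized order, each preceded by a baseline (120 s at ED15–18, 180 s at
ED9–14) and followed by an observation window of which 120 s are
analyzed. Analysis proceeds in 30-s intervals of `round(30 × frame_rate)`
frames — 1500 at 50 fps:

- four post-stimulus intervals (0–30 … 90–120 s) begin at the *release*
  frame, the moment the instrument leaves the beak;
- four pre-stimulus intervals are tiled backward from stimulus *onset*;
  the **baseline** is the median of their interval sums. Even at ED9–14,
  where three minutes of baseline exist, only the four intervals
  immediately preceding the stimulus enter the median.

Within each interval the per-frame values are summed (px·frames or
deg·frames). Missingness is handled in two steps, both operating on the
pre-imputation interval:

- **Exclusion**: an interval with strictly more than 5% missing frames is
  dropped (75 of 1500 retained, 76 excluded). Excluded pre-stimulus
  intervals are dropped from the baseline median rather than imputed; if
  all four are excluded the trial has no baseline for that parameter.
- **Imputation**: each contiguous missing run of length *g* is filled
  with one constant — the median of the `k = max(1, ceil(g/2))` nearest
  valid values on each side, pooled (one-sided at interval edges).
  "Half of the adjacent data" admits several readings; this one is
  symmetric, local, reduces to the nearest-neighbor median for g = 1, and
  never alters an observed value.

For contrasts and plotting the four baseline constituents collapse into a
single `BL` slot (the −30–0 s position) carrying the median.

## Contrast model

Interval sums from one embryo are correlated, so cell means (one per
window × interval combination) are estimated with a linear mixed model:
response = interval sum, fixed effect = cell, random intercept = embryo,
REML fit. Pairwise differences of estimated cell means are tested with a
family-wise adjustment in the Tukey style: each |t| is referred to the
distribution of the familywise maximum under the joint multivariate-t law
implied by the estimated contrast correlations (denominator df by
containment: observations − cells − embryos + 1; the multivariate-t box
probability is evaluated by seeded quasi-Monte Carlo, and adjusted
p-values are clipped to be at least the unadjusted ones). Significance is
declared at α = 0.05 (configurable).

The default comparison family per parameter covers the contrasts the
design is built to answer: every post-pinch interval against the pinch baseline and
against the same interval after touch.

Interval sums are heavy-tailed and heteroscedastic, which is why robust
(Huberized) mixed models are often preferred for such data. No robust-LMM
implementation is available to this package, so robustness is provided by a second, assumption-free route that is reported alongside
the REML fit: a **paired sign-flip permutation test**. Within-embryo
differences between two cells are randomly sign-flipped (the statistic is
the mean difference, making p-values invariant to affine rescaling of the
response); `p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm)`. For a family,
one shared set of per-embryo flips drives every comparison and each
statistic is referred to the permutation distribution of the familywise
maximum (max-|T|), controlling the family-wise error rate strongly. The
two routes must agree on the sign of every estimated difference; the test
suite checks this on simulated cohorts.

## Ethogram

Four observer-defined beak behaviors (BeakShift, Mandibulation,
BeakOpening, WideBeakOpening) arrive as frame-stamped events per trial.
Tallies count events and *responders* (embryos with ≥1 event) per ED
group × window × 30-s interval; for the manual-observation track the
baseline is the single 30 s immediately before each stimulus. Responder
percentages are rounded half away from zero to one decimal using integer
arithmetic (13/16 → 81.3, 3/16 → 18.8, 1/16 → 6.3) — the convention reported
percentages in this field follow, and one that binary floating point would
get wrong on exact ties. A threshold-crossing detector over the
beak-distance series proposes candidate opening events as an annotation
aid; candidates never enter the statistics.

## Synthetic cohorts

Real recordings of this protocol are rarely shareable, so the generator
produces pose tracks with the statistical structure the analysis assumes, with ground
truth recorded for every injected feature. Defaults are the protocol's
recording conditions: 50 frames/s, cohorts of 16 embryos at ED16, 120-s
baselines, ~2 s of clamp contact, 180 s of recorded observation.

- **Skeleton and noise**: fixed landmark geometry with isotropic Gaussian
  jitter (SD 0.5 px — sub-pixel, what a well-trained tracker achieves);
  per-embryo resting-gap offsets (SD 2 px) give the cohort a true
  random-intercept structure.
- **Beak gap**: rests at ~20 px; openings are trapezoidal pulses (0.25 s
  ramp, 1.5 s hold) — the simplest waveform with a controllable total
  open time. The pinch evokes on average 5 openings of 15 px in the first
  post interval, with rate and amplitude both decaying by 0.5 per later
  interval; the touch control evokes none (configurable). Spontaneous
  small openings (1/min, 3 px) and motility bouts displacing head and
  limb landmarks (2/min, 4 px, 1 s) run throughout the recording.
- **Degradation**: isolated dropouts (1% of frames) and occasional bursts
  push the likelihood below the cutoff and perturb the reported
  coordinates; rare outlier frames (5 × 10⁻⁴) displace a label by 300 px
  at high confidence.

The generator does **not** emulate gross posture changes that displace
the whole skeleton (the distortion that made ED9/ED12 beak tracking
uninterpretable in real recordings), correlated multi-landmark tracking
failures, slow camera or egg drift, or observer disagreement in the
ethogram. Passing recovery tests therefore shows the chain is correct and
well calibrated under its stated assumptions, not that those assumptions
hold for any particular real recording.

## Calibration results the suite computes

- With the default effect size (30× the landmark jitter; ≥5× is the
  tested condition) the full chain recovers a significant pinch-vs-
  baseline and pinch-vs-touch contrast at 0–30 s in ≥95% of 200 simulated
  cohorts (paired permutation, max-|T| adjusted, α = 0.05).
- Under a true null the permutation test's rejection rate over 1000
  replicates lies within the binomial 95% band around 0.05.
- On noise-free, dropout-free simulations the pipeline reproduces the
  generator's expected interval sums to floating-point accuracy, and
  reference-point movement is identically zero.

Problem sizes used by the test suite and the acceptance script: power
uses 200 cohorts of 16 embryos at full 50 fps timelines with 500
permutations per test; type-I calibration uses 1000 replicates at the
interval-sum level (the quantity the test actually consumes); unit and
property tests run reduced 5 fps timelines, which change frame counts but
no scientific content.

## Known limitations

- No Huberized robust-LMM route is provided; on
  heavy-tailed data the REML fit and the permutation test can disagree on
  borderline p-values (both are reported; the permutation route is the
  robust one).
- Denominator degrees of freedom use a containment heuristic rather than
  Satterthwaite; with 16 embryos and 10 cells the difference is
  immaterial, but tiny cohorts should rely on the permutation route.
- The outlier screen assumes artifacts are temporally isolated; a tracker
  that parks a label in a wrong location for many consecutive frames at
  high confidence will pass the screen (as it would pass most visual
  ones) and must be caught with the manual exclusion list.
- Imputation fills each gap with a locally constant value; it is meant
  for the ≤5% dropout regime the exclusion rule enforces, not as a
  general interpolator.
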