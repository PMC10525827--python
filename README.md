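# embryokin

Kinematic and ethogram analysis of stimulus-evoked movements of chicken
embryos (*Gallus gallus domesticus*) in ovo, from markerless
pose-estimation output.

Developing chicken embryos are widely used in research and routinely
culled in the poultry industry, yet when they become capable of
nociception — and hence when handling them raises welfare questions — is
an open empirical problem. One way to probe it is behavioral: apply a
noxious mechanical pinch and a light-touch control to the beak base, film
the embryo at 50 frames/s, track body parts with markerless pose
estimation, and ask whether movement after the pinch exceeds both the
pre-stimulus baseline and the touch control. `embryokin` implements that
analysis chain for anyone post-processing such recordings (or validating
the chain itself on simulated data):

1. **pose I/O** — the three-header-row (scorer/bodyparts/coords) CSV
   dialect and its HDF5 twin; role-based access to landmarks (beak tips,
   fulcrum, eye corner, elbow, metatarsus — tarsus at ED9); trial-design
   files describing stimulus timelines.
2. **QC** — a likelihood cutoff (default 0.75) masking low-confidence
   frames, and a reproducible outlier screen for single-frame tracking
   teleports (spatial robust distance **and** temporal discontinuity),
   with manual exclusion lists as an override.
3. **kinematics** — per frame: beak distance
   `d = √((xu−xl)² + (yu−yl)²)` (px), beak angle
   `α = atan2(|det[n₂ n₁]|, n₂·n₁)` at the fulcrum (deg, in [0, 180]),
   and landmark movement between consecutive frames (px).
4. **windowing** — 30-s interval sums (1500 frames at 50 fps), post
   intervals aligned to stimulus release, baseline = median of the four
   pre-stimulus interval sums; intervals with >5% missing frames are
   excluded, smaller gaps are filled with the median of the nearest
   ⌈gap/2⌉ valid neighbors per side.
5. **stats** — a linear mixed model (cell means, embryo random
   intercept) with Tukey-style family-wise adjusted marginal-mean
   contrasts, plus a paired sign-flip permutation test (max-|T| adjusted)
   as the robust companion.
6. **ethogram** — counts and responder percentages for the four beak
   behaviors (BeakShift, Mandibulation, BeakOpening, WideBeakOpening),
   rounded half away from zero to one decimal.
7. **simulate** — synthetic cohorts with known ground truth: skeleton +
   jitter, spontaneous motility, pinch-evoked beak openings decaying over
   the post window, dropouts, bursts and outlier frames.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

Simulate a cohort of 8 embryos at ED16, run the whole chain, and look at
the beak-distance contrasts:

```python
from embryokin.pipeline import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(outdir="demo_run", seed=7, n_embryos=8))
c = bundle["contrasts"]
print(c[c["parameter"] == "beak_distance"][
    ["method", "cell_a", "cell_b", "estimate", "p_adj", "significant"]
].to_string(index=False))
```

```
method           cell_a           cell_b    estimate        p_adj  significant
   lmm   PostPinch:0-30 BaselinePinch:BL 6488.146046 1.691750e-25         True
   lmm   PostPinch:0-30   PostTouch:0-30 6386.958728 3.766847e-25         True
   lmm  PostPinch:30-60 BaselinePinch:BL 2296.378181 3.071698e-07         True
   lmm  PostPinch:30-60  PostTouch:30-60 2263.309097 4.355025e-07         True
   lmm  PostPinch:60-90 BaselinePinch:BL  371.358406 8.923868e-01        False
   lmm  PostPinch:60-90  PostTouch:60-90  366.824691 8.979510e-01        False
   lmm PostPinch:90-120 BaselinePinch:BL   72.385198 9.999974e-01        False
   lmm PostPinch:90-120 PostTouch:90-120  110.713978 9.999511e-01        False
  perm   PostPinch:0-30 BaselinePinch:BL 6464.614238 1.649175e-02         True
  perm   PostPinch:0-30   PostTouch:0-30 6380.758027 1.649175e-02         True
  ...
```

Each row compares two window × interval cells of summed beak distance
(px·frames over 1500 frames). The simulated pinch evokes beak openings
whose rate and amplitude decay across the post window, and the analysis
recovers exactly that: a large, highly significant excess in the first
30 s after the pinch — relative to both the pre-pinch baseline (`BL`) and
the same interval after the harmless touch — shrinking at 30–60 s and
gone by 90–120 s. The mixed-model (`lmm`) and permutation (`perm`) routes
agree on every sign; permutation p-values are bounded below by
1/(n_perm + 1).

The run directory contains `qc_report.csv`, `kinematics.csv`,
`intervals.csv`, `contrasts.csv`, `tally.csv` and a `manifest.yaml`
recording every parameter; identical seeds give byte-identical outputs.

The same pipeline is scriptable from the shell:

```bash
embryokin simulate --n 16 --ed 16 --seed 1 --out cohort/
embryokin run-all --out run1 --n 16 --seed 1
```

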