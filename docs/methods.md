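# Methods

This note documents the models, numerical choices and limitations behind
`oculocog`, in the order the pipeline runs.

## Synthetic cohorts

The generator emulates a two-sample study design: a primary cohort
(default n=172; age 49.69 ± 7.58 years clipped to [18, 65]; 79% female;
education 13.5 ± 3.2 years) assessed with eye tracking and an 11-test
neuropsychological battery, and an independent normative sample (default
n=133) with test scores only.

A single latent ability factor g ~ N(0, 1) drives all outcomes. Each raw
test score is built from a unit-variance performance index

    v = λ·g − 0.30·age_z + 0.20·edu_z + 0.05·gender + noise,   λ = 0.5

mapped to the test's reference mean/SD (timed tests — TMT-A/B — flip
sign so larger values mean worse performance), clipped to each test's
observed range and rounded where the instrument is integer-valued. The
primary cohort's ability is shifted by −0.6 SD (a mildly impaired
population); its score marginals are re-centered on the battery's
reference statistics so the primary cohort, not the normative sample,
matches the published descriptive values. The single-factor structure is
the simplest that produces the shared signal the analysis assumes;
domain-specific factors, practice effects, and non-Gaussian score shapes
are not modeled.

### Eye-tracking features with a planted effect size

The four features load on g with a per-feature coefficient solved
analytically so that the *partial Spearman correlation* between the
feature and the non-MoCA composite (controlling age and education) hits
the configured `effect_rho` (default 0.25, the center of the
0.21–0.29 band the pipeline targets): the composite–g partial
correlation implied by the score model is computed in closed form, the
Spearman target is converted to its bivariate-normal Pearson equivalent
(r = 2·sin(πρ/6)), and the feature loading is their ratio. RMS features
load negatively on ability and take lognormal marginals (medians
0.45°/1.3°/1.0°, log-SD 0.35–0.45); the pupil reduction loads positively
and is truncated-normal 0.36 ± 0.09 clipped to [0.10, 0.95], matching
the detection criterion's floor. A mild age loading (0.15) makes the
demographic adjustment non-trivial. Monotone marginal transforms leave
Spearman structure intact, which is why the calibration survives them.

Recovery check (20 cohorts at n=172): mean |partial Spearman| 0.22–0.28
per feature, 0.25 overall.

### Raw traces

`generate_trace` synthesizes each task so the extraction path recovers
the planted values: gaze = (lagged, gain-scaled) target + slow
Ornstein–Uhlenbeck drift (τ = 0.25 s, 90% of the planted RMS variance) +
white tremor (10%), plus saccadic intrusions (outward smoothstep jump ≥2°
over 30 ms, 150–250 ms hold, corrective return; both logged as
ground-truth events). The intrusion rate scales with the planted RMS
squared so the saccadic contribution to RMS grows with — rather than
masks — the planted value. Pursuit targets are constant-velocity triangle
ramps (±8° at 8°/s) or an 8°, 0.25-Hz sine; the stated trajectories name
no kinematics, so these are package choices. The pupil task plants a
plateaued constriction of exact relative depth d (smoothstep over 0.8 s
after a 0.25 s latency, exponential re-dilation after LED offset), so
the noiseless extracted reduction equals d identically. Blinks are
Poisson gaps (0.08/s, 150 ms) with zeroed pupil signal. Distractors are
modeled only as a doubling of intrusion rate after 10 s; their geometry
is irrelevant to an RMS-based feature. Fatigue, vergence and binocular
disparity are not modeled, so passing tests say nothing about those
aspects of real recordings.

Feature missingness is completely at random at per-feature rates
(2.9/4.65/4.65/14.53%), reflecting technical signal loss rather than a
cognition-dependent mechanism; an informative-missingness regime is out
of scope. Trace-level blink loss adds a small amount of genuinely
technical missingness on top (pupil baselines with <50% valid samples
are dropped).

### The independent multimodal condition

`generate_multimodal_dataset` plants two *independent* latent components:
one observed through MoCA (integer, 26 ± 2.2, observation noise 0.25),
one through the four ET features (loading 0.55 each), with the altered
label drawn from their sum (equal weights, residual noise 0.8, median
split). Defaults were calibrated once so the three classifiers land in
the qualitative regime the pipeline is designed around — ET-only weakest
(≈0.68), MoCA intermediate (≈0.78), combined best (≈0.82) — and then
frozen. Under these defaults AUC(ET+MoCA) > AUC(MoCA) > AUC(ET) holds in
85–100% of 20-seed replicates.

## Preprocessing

* Blink margins: every maximal invalid run is dilated by 200 ms per
  side. A recording carries a `blink_masked` flag so the operation is
  idempotent; without state, re-applying dilation would eat the trace.
* Velocity: Savitzky–Golay first derivative, 21 ms window (rounded down
  to an odd sample count at the recording's rate; a configuration error
  if fewer than polyorder+2 samples), order 2, computed independently per
  contiguous valid segment. Samples within half a window of a gap edge
  are set missing — the filter never interpolates across a blink.
* Saccades: adaptive threshold initialized at 100 deg/s, iterated
  PT ← μ + 6σ over sub-threshold samples until the change is <1 deg/s;
  onsets/offsets extend to the μ + 3σ crossing; events merged when
  separated by <20 ms; minimum duration 10 ms. All constants are exposed
  in `SaccadeDetectionParams`. Event amplitude is the integral of speed
  over the event (an overestimate during drift, adequate for filtering).
  Against planted ≥2°, ≥20 ms events at default noise the detector scores
  recall ≈0.97 and precision 1.0 (±10 ms boundary tolerance).
* Degrees: a helper converts pixels using a 17″ 1280×1024 display at
  60 cm (pitch from the diagonal; deg = atan(px·pitch/distance)).

## Features

RMS error includes saccadic samples — the definition runs over the full
trial with only invalid (blink-masked) samples excluded; saccade
detection feeds fixation derivation, not the RMS. Target positions are
taken at gaze timestamps by nearest-sample lookup. The pupil minimum is
searched on a 50-ms moving average (raw 1000-Hz pupil noise would
produce spurious minima); the ≥10% criterion and both 1-s windows follow
the feature definitions; windows with under 50% of nominal valid samples
yield a missing feature.

The partial Spearman rank-transforms **all** variables (x, y and
covariates, midrank ties) and correlates the OLS rank-residuals — the
field-standard definition, numerically identical to
`pingouin.partial_corr(method="spearman")`, which serves as an
independent cross-check in the tests. p-values are t-based with n−k−2
df. No multiplicity correction is applied in the screen; retention is at
raw p < 0.05, and this is deliberate and documented rather than a
recommendation.

## Normative scoring

Per-test OLS with intercept, age, education and a binary gender
indicator, fitted only on the normative sample; σ is the residual SD
with an n−p denominator (unbiased scale). A rank-deficient design raises
an error naming the collinear predictor. Alteration is strictly
one-sided: z < −1 for higher-is-better tests, z > +1 for timed tests;
|z| exactly 1 is not altered. The TMT "B−A" contrast enters the first
executive composite as a difference in seconds with its own normative
fit (a quotient variant would also be defensible; the difference is the
package's choice). Missing member tests count as not-altered with a
logged warning, keeping composites defined. The global composite
(≥2 altered among all non-MoCA tests) is an aggregate indicator, not a
clinical diagnosis.

## Modeling

Imputation wraps scikit-learn's `IterativeImputer` (chained equations,
BayesianRidge default, `estimator="linear"` for exact deterministic
relationships — the Bayesian prior leaves a small shrinkage residual on
tiny noiseless problems). By default the imputer is fitted inside each
training fold and applied to its test fold; a flag restores global
pre-CV imputation for users who prefer imputation before modeling.
Cross-validation is 5-fold shuffled for regression and stratified for
classification; pooled out-of-fold predictions are the only basis for
metrics, and `CVResult.assert_out_of_fold` verifies the fold bookkeeping
on every run. RMSPE is 100·√mean(((y−ŷ)/y)²) with zero outcomes excluded
under a warning. MoCA weighting duplicates the MoCA column k times
before training (k=0 is ET-only; k=1 adds it once; larger k raises its
selection probability in tree construction). Hyperparameter search is
seeded random sampling over the documented spaces (tree depth,
estimators, subsampling, regularization; SGD loss/penalty/strength; MLP
depth/width/activation/dropout-analogue/learning rate/batch
size/early-stopping patience; class weighting for the random forest),
80 configurations by default.

## Evaluation

AUC uses the trapezoidal rule with midrank tie handling (equal to the
normalized Mann–Whitney U), so a constant score gives exactly 0.5 and
integer MoCA scored against its own cutoff gives exactly 1.0. The
screening threshold maximizes specificity subject to sensitivity ≥0.85,
falling back to maximal sensitivity when unattainable. McNemar uses the
continuity-corrected χ² on discordant errors with an exact two-sided
binomial below 25 discordant pairs, and (χ²=0, p=1) by convention with
none. Permutation importance permutes one column at a time (50
permutations) and re-scores the pooled out-of-fold predictions using
each fold's fitted model on its own held-out participants, reporting the
mean AUC decrease ± SD.

## Problem sizes and determinism

The analysis drivers and the acceptance summary use 20-replicate
experiments at the study sizes (n=172 / n=133), 10-s fixation traces at
1000 Hz for detector scoring, and 250-Hz example traces where only
illustration is needed; these sizes give stable estimates at desk scale.
Every stochastic step takes an explicit seed; identical configurations
reproduce cohort and feature tables bit-identically (the pipeline writes
a SHA-256 manifest of its artifacts).

## Known limitations

Synthetic traces cannot stand in for hardware-specific artifacts
(EyeLink host filtering, calibration drift, monocular dropouts), and the
single-factor cognition model understates the heterogeneity of real
impairment. Null calibration and effect-recovery results therefore
validate the *pipeline's statistics*, not any clinical claim. Classifier
AUCs quoted here describe the synthetic planted conditions; real-data
performance depends on effect sizes the generator only emulates.
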