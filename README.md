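# oculocog

Eye tracking offers a fast, language-free window on cognition: fixation
stability, smooth-pursuit accuracy and the pupillary light reflex all
degrade with the subtle, multi-domain impairment seen in conditions such
as post-COVID cognitive dysfunction. `oculocog` implements a complete
analysis pipeline from raw gaze traces to screening-oriented classifiers,
together with a synthetic-data generator that reproduces the statistical
structure such a study assumes — so every stage can be validated without
access to clinical recordings.

The pipeline has five stages:

1. **Preprocessing** — blink margins (200 ms either side of each invalid
   run), velocity from a 21-ms second-order Savitzky–Golay derivative,
   saccade detection with a noise-adaptive velocity threshold
   (PT<sub>k+1</sub> = μ<sub>k</sub> + 6σ<sub>k</sub> iterated to
   convergence), fixation samples as the valid non-saccadic remainder.
2. **Features** — per participant: fixation RMS error under distractors,
   smooth-pursuit RMS for sinusoidal and vertical trajectories

   RMS = √( (1/N) Σᵢ (x<sub>gaze,i</sub>−x<sub>stim,i</sub>)² + (y<sub>gaze,i</sub>−y<sub>stim,i</sub>)² )

   and the relative pupil-area reduction (B−C)/B, with B the mean area in
   the 1 s before LED onset and C the mean over 1 s from the first
   post-onset local minimum showing ≥10% constriction. A partial Spearman
   screen (controlling age and education) checks each feature's
   association with the neuropsychological battery.
3. **Labels** — expected test scores from an OLS fit (age, education,
   gender) on an independent normative sample; z = (observed −
   expected)/σ<sub>normative</sub>; altered when |z| > 1 in the impaired
   direction (reversed for timed tests); MoCA altered at the raw <26
   cutoff; domain composites altered when ≥2 member tests are; a global
   composite over all non-MoCA tests.
4. **Models** — 5-fold out-of-fold regression (OLS, SGD, gradient-boosted
   trees, random forest, MLP; pooled R² and RMSPE) and classification
   (LDA, random forest), with chained-equations imputation inside training
   folds and MoCA weighting by column duplication for the multimodal
   classifier. Seeded random search over the documented hyperparameter
   spaces (80 configurations).
5. **Evaluation** — pooled ROC/AUC and precision–recall, operating
   thresholds guaranteeing sensitivity ≥ 0.85, confusion matrices with
   row percentages, McNemar tests on paired errors, and permutation
   feature importance (mean AUC decrease over 50 permutations).

## Worked example

```python
import oculocog as oc

cfg = oc.CohortConfig(seed=20260929)          # n=172 primary, n=133 normative
normative, primary = oc.generate_cohort(cfg)
features = oc.planted_feature_values(primary, cfg, seed=1)

model = oc.fit_normative(normative)
labels = oc.label_cohort(model, primary)
y = labels["global"].to_numpy().astype(int)

res = oc.run_classifier(
    features[["fix_rms_distractors", "sp_rms_sinusoidal",
              "sp_rms_vertical", "pupil_reduction", "age"]],
    y, model="rf", moca=primary["moca"].to_numpy(),
    moca_weight=2, seed=0,
)
report = oc.evaluate_classifier(res.predictions, y)
print(round(report.auc, 3), round(report.confusion.sensitivity, 2),
      round(report.confusion.specificity, 2))
```

which prints `0.685 0.86 0.37`: the multimodal random forest separates
globally altered from unaltered participants with AUC 0.685 on this
single-factor cohort, and the screening threshold holds sensitivity at
0.86 at the cost of specificity 0.37.

Running the numbered drivers reproduces the full analysis; for example
`python analysis/05_evaluate_screening.py` prints (among more detail):

```
operating points (threshold chosen for sensitivity >= 0.85):
  RF-ET: AUC=0.689 sens=0.86 spec=0.35
  RF-ET+MoCA: AUC=0.799 sens=0.86 spec=0.53
  MoCA @ <26: AUC=0.747 sens=0.59 spec=0.76
```

i.e. on the synthetic multimodal condition the combined eye-tracking +
MoCA classifier discriminates best (AUC 0.80), and at a screening
threshold it keeps sensitivity at 0.86 while roughly halving the false
positives of the ET-only model; the fixed MoCA cutoff alone trades
sensitivity away for specificity. `analysis/06_calibration_checks.py`
verifies the generator: a planted feature–cognition partial Spearman of
0.25 is recovered (0.246 over 20 cohorts), the saccade detector scores
recall 0.98 / precision 1.00 against planted event logs, and with no
planted signal classifiers sit at AUC 0.515 ± 0.05.

There is also a thin CLI (`oculocog synth|labels|model|run-all`) over the
same library functions.

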