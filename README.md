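# foveage

Quantifying foveal microstructure from OCT-derived retinal thickness
profiles and relating it to chronological and biological (PhenoAge) age.

The fovea — the central retinal depression responsible for high-acuity
daylight vision — is remarkably variable between healthy people but, as
far as its pit geometry goes, remarkably stable across adult life. The
question this package addresses is whether foveal microstructure tracks
*biological* aging (a blood-biomarker clock) any more closely than it
tracks calendar time, and which foveal features change with age at all.
It is written for retinal-imaging researchers who want a tested, fully
reproducible implementation of that analysis chain, runnable end to end
on seeded synthetic cohorts.

The pipeline has five stages, each usable on its own:

* **`foveage.synthetic`** — a seeded cohort generator: paired eyes with
  within-participant correlation, Gaussian-deficit ILM thickness
  profiles, ellipsoid-zone (EZ) height profiles with or without the
  foveal bulge, and nine-biomarker panels whose PhenoAge is targeted
  exactly.
* **`foveage.morphometry`** — pit morphometry on 1-D thickness profiles:
  the pit floor is the thickness minimum; the pit edges are the points
  where the first derivative of the ILM profile falls back to 50% of
  each side's maximum slope (with 40%/60% sensitivity analysis); from
  these follow central foveal thickness (CFT), pit depth (floor to the
  edge-to-edge reference chord), pit diameter and mean wall slope, plus
  an algorithmic surrogate detector for the EZ foveal bulge.
* **`foveage.phenoage`** — biological age from nine routine blood
  biomarkers plus chronological age via the Gompertz-mortality PhenoAge
  algorithm, with the CRP > 10 mg/L acute-inflammation exclusion.
* **`foveage.paired_stats`** — Me [IQR] descriptives, Wilcoxon
  signed-rank and McNemar right/left comparisons (exact for small
  samples), Wilson prevalence intervals, Cohen's kappa, and the
  noncentral-F minimum-detectable-R² power computation.
* **`foveage.age_models`** — for every parameter and both age metrics,
  three candidate mixed models with a participant random intercept
  (constant, linear, penalized thin-plate-style spline with basis
  dimension k ∈ {5, 10, 15, 20}), all fitted by ML and compared by AIC;
  Wald tests on the linear age term with Benjamini–Hochberg adjustment;
  population predictions for ages 17–92 with 95% CIs and prediction
  intervals; four age-group summaries; per-year odds ratios for the
  bulge; Spearman correlations.

The core statistical model for a continuous parameter y of eye j in
participant i is

    y_ij = f(age_i) + u_i + e_ij,   u_i ~ N(0, τ²),  e_ij ~ N(0, σ²)

with f constant, linear, or a penalized spline, and the analogous
random-intercept logistic model for bulge presence:

    logit P(bulge_ij) = α + β·age_i + u_i,   OR per year = exp(β).

`analysis/01…06` are thin numbered drivers that run the stages in order
and write their tables under `results/`; `foveage.pipeline.run_pipeline`
(or `foveage run`) does the whole chain in one reproducible call.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 42
python analysis/04_compare_eyes.py   --seed 42
```

prints (abridged):

```
cohort: 154 participants, 308 eyes (seed 42)
age 54.7 +/- 18.4 y (22-87)
PhenoAge 51.3 +/- 20.6 y; accel -3.4 +/- 8.5 y; r(age, PhenoAge) = 0.912
bulge prevalence (truth): 68.2%

                      parameter                   right                    left  p_value     test
     Foveal thickness (microns)    204.5 [184.5, 217.1]    203.2 [184.2, 217.9]     0.54 wilcoxon
     Foveal pit depth (microns)     100.0 [81.6, 112.7]      98.9 [83.9, 111.3]     0.61 wilcoxon
  Foveal pit diameter (microns) 1240.2 [1040.1, 1406.4] 1236.1 [1039.3, 1396.5]     0.96 wilcoxon
   Foveal slope steepness (deg)         8.8 [7.3, 11.1]         8.7 [7.2, 11.0]     0.86 wilcoxon
Presence of foveal bulge, n (%)             108 (70.1%)             102 (66.2%)     0.50  mcnemar

post hoc power: minimum detectable R^2 = 0.049 (n = 154, power 0.80, alpha 0.05)
```

Reading this: right and left eyes are statistically indistinguishable on
every pit parameter (all p > 0.05), the measured pit depth and diameter
medians sit where the generator was calibrated to put them, and about
two-thirds of eyes carry a foveal bulge.  Running
`python analysis/05_model_age_trends.py --seed 42` then shows the
headline contrast: the constant (no-age) model wins AIC for all four
continuous parameters under both age metrics (adjusted p ≥ 0.92), while
bulge prevalence declines significantly with age (OR ≈ 0.96 per year,
adjusted p < 0.01, model-predicted prevalence falling from ~0.8 in the
youngest group to ~0.5 in the oldest).

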