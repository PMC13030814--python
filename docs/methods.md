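# Methods

## Synthetic cohort model

The generator produces the study conditions the analysis assumes rather
than mimicking any particular device's raw output.  One cohort consists
of `n_participants` (default 154) participants with ages drawn uniformly
on [22, 89] years, each contributing a right and a left eye (308 eyes at
the default size).

**Pit geometry.** Each participant gets true pit parameters — rim
thickness, pit amplitude and pit width — drawn from independent normals
and clipped to physiological ranges; each eye perturbs them with a small
jitter (SD 5 µm on rim/amplitude, 10 µm on width), which yields
inter-eye correlations above 0.9 and realizes the within-participant
correlation that the mixed models later absorb.  Geometry is independent
of age *by construction*: the age-trend analysis on synthetic data has a
known truth (no trend), which is what the model-selection and
null-calibration tests rely on.

The ILM thickness profile of an eye is a single-Gaussian deficit

    T(x) = rim − amp · exp(−x² / (2σ²)) + ε,   ε ~ N(0, 2 µm),

sampled every 5 µm over ±2500 µm.  The model is deliberately minimal:
its derivative is closed-form, so every morphometric quantity has an
analytic oracle.  At the 50% derivative threshold the outer crossing
sits at u·σ with u = 1.9216 (the root of u·e^(−u²/2) = ½·e^(−½)), giving
depth = 0.8434·amp and diameter = 3.843·σ.  The defaults amp = 113 µm
and σ = 326 µm are these relations inverted at the healthy-adult
reference medians (95 µm depth, 1252 µm diameter); the SDs (25 and
70 µm) are the reference IQR widths divided by 1.349 and propagated the
same way.  Rim thickness defaults to 280 ± 15 µm.  Note that the 1-D
CFT surrogate (mean thickness over the ±500 µm segment) is
systematically below the 2-D central-subfield disc average reported by
devices, by roughly 50–60 µm for these shapes; it is internally
consistent but not comparable to instrument CFT values.

**Foveal bulge.** Bulge presence is generated per eye from a
random-intercept logistic model, logit p = α + ln(OR)·age + u_i with
u_i ~ N(0, 1 logit) and OR = 0.949 per year by default; α is solved
numerically (Gauss–Hermite over u, quadrature over the age
distribution) so the marginal prevalence is 0.685.  The driving age may
be chronological age or the participant's PhenoAge (for the
biological-age recovery study).  The EZ height profile is flat (absent)
or carries a central Gaussian elevation of 10 µm, σ = 100 µm (present),
plus 1 µm noise.  The surrogate detector calls a bulge when the mean EZ
height within ±50 µm of center exceeds the 400–600 µm annulus on both
sides by ≥ 2 µm; at the default settings it agrees with the generating
truth in ≥ 99% of eyes.  Real bulge grading is a human visual judgement
on B-scans; the detector exists so the synthetic pipeline is end-to-end
executable, and nothing downstream depends on its specific form.

**Biomarkers.** A participant's panel is built backwards from a target
PhenoAge = age + N(−3.6, 7.8) years.  Eight biomarkers (albumin,
creatinine, lymphocyte %, MCV, RDW, ALP, WBC, CRP) come from
age-indexed reference normals centered on standard adult reference
intervals; each carries a loading on the standardized acceleration draw
(e.g. +0.7% RDW and −1.5 g/L albumin per SD of acceleration), so a
biologically old participant's whole panel shifts in the aging
direction, as real panels do.  Glucose is then solved exactly from the
PhenoAge linear predictor, so `phenoage()` on a generated panel returns
the target to machine precision.  If the solved glucose leaves
[2.5, 25] mmol/L it is pinned at the bound and CRP re-solved (CRP enters
through ln, is continuous, and has room in [0.05, 10] mg/L); failing
that, the draw — including the target — is rejected and redrawn, with a
retry cap.  Without the loadings the entire ±7.8 y acceleration would
have to pass through glucose alone, which truncates the acceleration
distribution badly; with them the realized acceleration is
−3.9 ± 7.8 y and the PhenoAge–age correlation 0.93 on large draws.  A
configurable fraction (default 2%) of panels draw acute-phase CRP
(> 10 mg/L) to exercise the exclusion filter.

**What the generator does not emulate:** 2-D/3-D scan structure,
device segmentation error, vascular/choroidal features, pathology, axial
length magnification, and any real covariance between pit shape and the
biomarker panel.  Tests passing on this generator show the *pipeline* is
correct and calibrated under the stated statistical structure; they say
nothing about segmentation quality on real B-scans.

## Morphometry

All measurements run on a Savitzky–Golay-smoothed profile (55 µm window,
order 2; polynomials up to the order are reproduced exactly).  The pit
floor is the global thickness minimum (ties broken toward the center); a
minimum at a grid end means no pit.  For edge detection, each side's
derivative threshold is `fraction × that side's maximum |slope|`, and
the edge is the first crossing beyond the maximum-slope point where the
|derivative| falls back to the threshold, linearly interpolated between
grid points.

Two estimator choices matter at realistic noise and are worth recording.
First, the edge-detection derivative is the slope of a local *quartic*
fit over a 405 µm window (SG deriv = 1), not a central difference of the
smoothed profile: the threshold rule compares the derivative's tail with
a fraction of its peak, and the central-difference estimate leaves
noise (SD ≈ 0.08 µm/µm) comparable to the threshold itself (≈ 0.11),
which biased diameters by −3.7% and aborted on a few percent of
profiles.  The quartic window keeps the systematic error on
Gaussian-pit walls ≤ 0.4% over σ ∈ [250, 450] µm and the noise-induced
bias ≈ 0.3%.  The outermost half-window at each scan end is excluded
from the peak/edge search because the boundary polynomial fit is
unreliable there.  Second, the pointwise mean wall slope uses the SG
derivative at the smoothing window (55 µm): arctan|d| of a
central-difference estimate absorbs noise near the flat floor and
biased the mean slope by +2.7%; the SG version is +0.6%.  The public
`profile_derivative` remains a plain central difference (exact for
linear profiles) for use where its simplicity is the point.

Pit depth is the edge-to-edge chord evaluated at the floor position
minus the floor thickness; diameter is the edge separation; CFT is the
mean over the ±500 µm segment centered on the floor.  The slope can
alternatively be computed as the edge-to-floor chord angle
(`method="chord"`); the pointwise mean is the default.  The sensitivity
report re-measures one smoothed profile at 40/50/60% thresholds and
reports pairwise relative differences normalized by the larger of the
two values; on default-shaped pits the extreme-threshold depth
difference stays below 10%.

## PhenoAge

The linear predictor combines the nine biomarkers and chronological age
with the published weights (shipped in
`src/foveage/data/phenoage_coefficients.json`; the module verifies the
file's SHA-256 and refuses altered constants).  CRP is stored in mg/L —
the scale of the exclusion threshold — and enters as ln(mg/dL).
Mortality risk over a 120-month horizon follows the Gompertz form
M = 1 − exp(−e^xb·(e^(120γ)−1)/γ) with γ = 0.0076927, clamped to
[1e−12, 1−1e−12] before the log-log inversion onto the year scale.
PhenoAgeAccel is PhenoAge minus chronological age.  The exclusion filter
drops rows with CRP strictly greater than 10 mg/L (a value of exactly
10 is retained) and reports the excluded ids.  Creatinine is taken in
µmol/L and albumin in g/L; the constants file documents every unit.

## Paired statistics

Quartiles use linear interpolation between order statistics.  The
Wilcoxon signed-rank test drops zero differences and uses tie-averaged
ranks; for ≤ 25 informative pairs the two-sided p comes from the exact
null distribution (dynamic programming over doubled ranks, identical to
full sign enumeration, which the tests verify by brute force up to
n = 12), otherwise a continuity- and tie-corrected normal
approximation.  McNemar's test is the exact binomial on the discordant
counts when b + c < 25, else the continuity-corrected chi-square.  The
25-pair switchover is a package choice.  Prevalences carry Wilson score
intervals (clamped to contain k/n against floating-point dust at the
boundaries).  The minimum detectable R² solves the noncentral-F power
equation for a single-predictor fixed-effects regression with
noncentrality λ = f²·n by bisection; at n = 154, 80% power, α = 0.05
this gives R² = 0.0491.  A closed-form minimum-detectable effect is only
standard for fixed-effects regression, so this is the model the power
computation uses even though the trend analysis itself is mixed.

## Age-trend models

All candidates for one outcome are fitted on identical rows by maximum
likelihood (not REML), so AICs are comparable across fixed-effect
structures; AIC = −2ℓ + 2k with k counting fixed effects plus variance
parameters.

*Gaussian outcomes* use a purpose-built profiled-ML linear mixed model:
for given variance ratios the GLS coefficients and σ² are closed-form,
leaving a 1–2 dimensional optimization over log ratios (dense Cholesky;
n is a few hundred).  It matches statsmodels MixedLM (ML) to 5+ digits
on constant/linear fits — the tests assert this.  The spline candidate
adds a truncated-power cubic basis ((age − κ_j)³₊ at k − 2 interior
quantile knots) whose coefficients enter as a variance component: the
classical mixed-model form of a penalized smooth.  The smoothing
parameter is thus estimated by ML alongside τ² and σ², and the smooth's
effective degrees of freedom (1 + trace of the wiggle influence) shrink
to 1 when the data carry no curvature — on null geometry the selected
spline's edf lies in [1, 1.5] in ≳95% of seeds.  The basis dimension k
runs over {5, 10, 15, 20}; the best k is chosen by AIC first, then
constant/linear/best-spline compete.  Ties (ΔAIC < 1e−6) go to fewer
parameters.

*Binomial outcomes* (bulge presence) use a purpose-built
random-intercept logistic model maximized over (β, ln τ) with 20-node
Gauss–Hermite quadrature; no pre-installed Python package provides a
frequentist GLMM.  On a fixed paired-eyes fixture it reproduces
lme4::glmer (nAGQ = 20) coefficients, standard errors, τ and
log-likelihood to ~4 decimals (frozen in the tests), and it collapses to
ordinary logistic regression when the variance component vanishes.  The
binomial spline candidate uses the same basis unpenalized (edf = number
of smooth columns); it is there so the AIC loop is complete, and it
essentially never wins on realistic bulge data.  Ages are standardized
internally for conditioning and mapped back for reporting.

The Wald p for the *linear age term* is always taken from the linear
candidate, whichever structure wins AIC, and the ten p-values
(4 continuous + bulge, × 2 age types) are Benjamini–Hochberg adjusted
jointly (statsmodels step-up, order preserved).  AICc is not used; AIC
is the selection criterion throughout.

Population predictions exclude random effects and run over ages 17–92
in 1-year steps (extrapolating a little beyond the sampled 22–89 range,
as reference curves conventionally do; ages outside 17–92 require an
explicit flag).  The 95% CI is ±1.96 SE of the fixed-effect predictor.
The prediction interval adds the random-intercept and (Gaussian)
residual variances; for the binomial model both intervals are built on
the logit scale — the PI inflated by the random-intercept SD — and
inverse-transformed.  A "prediction interval" for a Bernoulli outcome is
not a standard object; the logit-scale inflation is this package's
interpretation of a plausible-range band for a new participant's
probability, and it is wide by design.  For a constant Gaussian fit the
CI uses the intercept SE only; for the penalized-spline fit the CI
tracks the parametric (intercept + linear) part, with the smooth's
contribution entering the point prediction.  Curve values are averaged
within the four age groups 17–44, 45–59, 60–74, 75–92 (unweighted over
integer ages), with per-group eye counts from the data.

## Pipeline

`run_pipeline` executes simulate → measure → PhenoAge → CRP filter →
paired comparisons → models, writes every table as CSV next to a
resolved copy of the configuration and a timestamped log, and is
bit-reproducible given the seed (the log's timestamps are the only
non-deterministic output).  The CRP filter runs before modeling and its
counts are logged.  Significance labels follow the convention
p < 0.05 significant, 0.05 ≤ p < 0.1 a tendency, otherwise ns.

## Problem sizes

Default runs use the study-scale cohort (154 × 2 eyes).  The
odds-ratio recovery studies use 200 replicate cohorts per age metric;
the null model-selection and edf properties use 100 seeded cohorts; the
noise-robustness checks use 150–300 noisy profiles; the PhenoAge
correlation uses 2000 draws.  The full test suite runs in about 2½
minutes on one CPU.

## Known limitations

* The morphometry operates on 1-D profiles; real central-subfield
  thickness and 2-D pit metrics are not comparable without a disc
  integration, and no magnification (axial-length) correction is
  applied.
* The bulge detector is a synthetic-data surrogate, not a validated
  grader; inter-rater agreement statistics (kappa, agreement rate) are
  provided as computations, not as claims about the detector.
* The binomial "prediction interval" is an interpretation (see above).
* The Gaussian spline CI ignores smooth-coefficient uncertainty; on
  null-trend data this is immaterial because the smooth shrinks away.
* Power analysis uses the fixed-effects approximation.
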