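# Methods

This note documents the models and procedures implemented in `slice3bc`,
the defaults chosen where the underlying workflow left the design open, and
what the synthetic generators do and do not emulate.

## The measurement model

Whole-body composition by MR volumetry rests on three steps.

**Tissue classification.** On T1-like contrast, adipose tissue (AT) is
bright and lean tissue intermediate, so a single intensity threshold on the
body-restricted histogram separates the two classes. The package assumes
bright-is-fat and asserts it in the phantom model; an `invert` flag covers
the opposite convention. Adipose-tissue-free mass (ATFM) is defined by
subtraction — body area minus AT area — which makes area conservation
(`AT + ATFM = body`) an identity rather than an empirical property.

Two cleanup rules replace the interactive slice editing of expert
workflows:

* *Partial-volume removal*: connected AT components smaller than
  `min_component_px` are dropped. Default 9 px (a 3×3 dot at typical 2 mm
  spacing); the size cutoff is a calibration choice, not a measured value.
* *Weak-subcutaneous recovery*: thresholding loses subcutaneous fat where
  the signal dips. The package closes the AT label morphologically,
  jointly with the outside-of-body region (so surface dropouts close
  against the body boundary), restricted to a peripheral band of the body
  mask `ring_width_px` wide (default 3 px). Restricting to the band keeps
  visceral/interior structure untouched; the operation is provably
  idempotent (closing is idempotent and monotone, and the added pixels are
  a subset of the closure).

The body outline itself is the largest connected above-background
component after a 3×3 opening (which stops background noise from grafting
a fringe onto the body), holes filled. The background level is an
intensity quantile (default 0.6) — appropriate when the body occupies
clearly less than half the field of view, as in axial body imaging.

Threshold selection defaults to Otsu's between-class-variance criterion; a
valley search (deepest smoothed-histogram minimum between the two dominant
modes) is available because "histogram analysis" does not pin down a
method. On well-separated bimodal data the two coincide; the method and
threshold are logged with every segmentation.

**Slice volumetry.** `V = A × t` with t = 10 mm. Whole-body volumes from
the 41-slice reference series use the truncated-pyramid (frustum) rule
between consecutive slices, `V = (h/3)(A₁ + A₂ + √(A₁A₂))`, which is exact
whenever the section area is the square of a linear function of axial
position (prisms, cones, pyramids and their frusta). Two conventions the
protocol leaves open are fixed and configurable:

* *Inter-slice distance*: h = 50 mm, centre-to-centre (10 mm thickness +
  40 mm gap). "Spaced by 40 mm" could also mean 40 mm centre-to-centre;
  the centre-to-centre reading keeps slices non-overlapping and is the
  default.
* *End caps*: the first and last slices contribute their own
  half-thickness (5 mm) prisms, so a constant-area series reduces exactly
  to area × imaged extent.

Masses use constant densities 0.92 kg/L (AT) and 1.04 kg/L (lean),
overridable only through configuration.

**Prediction.** The published equations map three slices plus
anthropometrics to whole-body masses:

```
AT   = −12.74105 + 0.02919·age + 4.27634·sex + 0.22008·weight
       + 26.92234·AT_T6T7 + 23.70142·AT_L4L5 + 37.94739·AT_midthigh
ATFM = −33.10721 − 0.02363·age − 3.58052·sex + 30.02252·height
       + 0.08549·weight + 11.36859·ATFM_T6T7 + 27.82244·ATFM_L4L5
       + 58.62648·ATFM_midthigh
```

with sex coded M = 0 / F = 1, age in years, height in metres (the 30.02
coefficient, ≈ kg per metre of stature, only makes sense in metres),
weight and slice masses in kg. The coefficients are shipped as the
immutable `text-v1` variant. A `table-v1` variant preserves the
tabulated printing of the same equations verbatim, including its defects
(a 4.24634 sex coefficient, a duplicated 37.94739 column, a sex sign
flip); it exists for traceability and is never the default.

## Model re-derivation

`fit_ols` is ordinary least squares (statsmodels) with
`SEE = √(RSS/(n − p − 1))` and AIC in the `n·ln(RSS/n) + 2(p+1)`
convention of R's stepwise tooling — comparable across models on the same
data but offset from conventions that keep the Gaussian constant, so
absolute AIC values are not comparable across software.

`select_stepwise_aic` is greedy single-move search: forward from the
intercept, backward from the full model, or bidirectional from the full
model; `select_best_aic` runs all three and flags the lowest-AIC model,
mirroring how the final published variant was kept. Note that AIC's
penalty of 2 per parameter retains a pure-noise regressor with probability
≈ P(χ²₁ > 2) ≈ 0.16; "selection consistency" claims for AIC are therefore
soft, and the tests assert exclusion rates accordingly.

`cooks_filter` removes observations whose Cook's distance exceeds a rule —
default `4/n`, with the conservative classic `D > 1` available — refitting
at most twice and aborting if more than 10% of rows would go. The `4/n`
rule flags about 5% of clean Gaussian rows at n = 310, so with that
default a handful of removals on clean data is expected behaviour, not a
defect; `D > 1` removes essentially none.

`residual_diagnostics` reports Durbin-Watson (pass inside 1.5–2.5),
Shapiro-Wilk, and Bartlett's test across tertiles of the fitted values
(the grouping had to be chosen; fitted-value tertiles are the natural
heteroscedasticity axis). Below 8 residuals the diagnostics are
suppressed with a notice.

## Agreement statistics

Lin's CCC uses population (1/n) moments — Lin's original definition; with
sample moments the value changes in the third decimal at n ≈ 300. The
confidence interval is the Fisher-z normal approximation with
`SE = 1/√(n − 3)`; at CCC 0.986, n = 310 it reproduces the reference
interval (0.982–0.989) to three decimals. Bland-Altman limits use the
1.96 multiplier and the sample (n−1) SD of differences. The Wilcoxon
signed-rank test drops zeros (Wilcoxon's original treatment), mid-ranks
ties, and computes the exact two-sided p over all 2ⁿ sign assignments (by
convolution over doubled ranks) up to n = 25, switching to a normal
approximation with continuity and tie corrections above. Subgroup reports
(by sex, or BMI class <25 / 25–30 / >30) flag groups below n = 15 as
wide-CI, since the Fisher-z interval becomes uninformative there.

## Synthetic generators

**Slice phantoms** are elliptical bodies with a constant-thickness
subcutaneous fat ring and optional disjoint visceral fat discs inside the
lean region. Ground truth is dual: closed-form areas (ellipse ring +
discs) and pixel counts on the noise-free label grid, which differ only by
pixelisation (< 1 perimeter pixel row). Noise is additive Gaussian on the
magnitude image — adequate at phantom SNR and simpler to reason about than
Rician noise, whose bias matters only near the noise floor. Defaults
(semi-axes 150 × 100 mm, 20 mm ring, 1000/200/0 a.u. intensities, 2 mm
pixels) give a realistic abdominal fat fraction (~30% of body area).

**Series phantoms** scale the base geometry linearly along the axis, so
cross-sectional areas vary as the square of a linear function — the regime
where frustum reconstruction is exact up to end-cap treatment. The truth
volumes integrate the analytic area profile with a 10 000-panel trapezoid
rule, an oracle independent of the estimator under test.

**Cohorts** draw the nine covariates (age, height, weight, six slice
masses) from a Gaussian copula with truncated-normal marginals whose
underlying parameters are *moment-matched*: solved so the truncated
distribution has exactly the target mean and SD inside the stated
physiologic range. Without this, asymmetric ranges (age 20–66 around
50.8 ± 10.6) would distort the realised SD by up to ~14%. Only marginal
summaries of the development cohort are published, so the joint structure
is a stated, overridable default: weight correlates 0.7 with every slice
mass, slice masses 0.5 with each other, all remaining pairs 0.3. The
slice-slice value cannot drop much below 0.4: with six slices each at 0.7
with weight, weaker mutual correlation makes the matrix indefinite. Sex
is independent Bernoulli (female fraction 70/310) — a simplification; in
reality men are taller and heavier, which matters only for analyses that
interact sex with anthropometrics, none of which the package performs.

Measured totals are the published equations plus Gaussian residuals at
the printed standard errors of estimate (AT 2.18 kg, ATFM 2.69 kg). This
makes the generator *self-consistent with the published fit* rather than a
model of raw anatomy: refitting on such cohorts must recover the printed
adjusted R² and CCC if — and only if — the covariate dispersion matches
the development cohort. That dispersion is set by `calibrate_slice_sds`,
which scales the three slice-mass SDs (ranges widened proportionally,
lower bounds clipped at a small positive mass) by a factor found by
root-finding so the equation's linear predictor has the SD implied by the
printed response SD and SEE (AT: √(13.27² − 2.18²) ≈ 13.09 kg; ATFM:
√(10.29² − 2.69²) ≈ 9.93 kg). The default (uncalibrated) spec yields a
predictor SD of ≈ 12.2 kg, i.e. the headline R² is *not* baked in — it
emerges from the calibrated dispersion plus the published noise level.

**Longitudinal tables** add per-subject Gaussian changes to the measured
totals, co-shift the slice masses proportionally (no per-slice change
model is published; a uniform relative change is the neutral choice) and
track weight by the summed mass change. The proportional co-shift keeps
the prediction equations approximately — not exactly — unbiased at
follow-up: the weight and slice terms reproduce roughly 90% of an
injected change, so paired method-difference tests on large subgroups can
detect the residual, which is faithful to how such equations behave.

The generators do **not** emulate: realistic anatomy (bone, organs),
field inhomogeneity, scan-rescan variation (a test-retest precision range
is known but no within-subject noise model), or sex-dependent covariate
distributions. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model of the development cohort,
not segmentation accuracy on clinical images.

## Problem sizes and numerical choices

Monte-Carlo checks use 20–100 seeded replicates (20 cohorts of n = 310
for the headline refit summaries; 100 runs for selection-rate checks;
1000 cheap replicates for test-size checks), sizes at which the
Monte-Carlo error is well below the asserted tolerances. Reduced phantom
series (5–9 slices, via the explicit `allow_short` override) stand in for
the 41-slice protocol in geometry tests, since frustum exactness and the
integration oracle are length-independent. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`/`SeedSequence`;
identical (spec, seed) inputs give bit-identical outputs. Degenerate
inputs (constant histograms, zero-variance differences, CCC at ±1,
all-zero Wilcoxon differences) return flagged results or raise named
errors rather than NaNs.

## Known limitations

* The segmentation is two-class only; visceral vs subcutaneous
  compartments, bone exclusion and bias-field correction are out of scope.
* The prediction equations are population-specific (French adults, mostly
  overweight/obese); the package makes no generalisability claim and
  provides the refitting machinery precisely so new populations can
  derive their own coefficients.
* The frustum end-cap convention (half-thickness prisms) and the 50 mm
  centre-to-centre distance are documented interpretations of an
  under-specified protocol; both are configurable.
* Published AIC values are not reproducible without the raw data (the
  additive constant and the exact sample after outlier removal are
  unknown) and are not targets anywhere in the package.
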