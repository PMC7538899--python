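# Methods

`octlayers` implements the quantitative core of a longitudinal OCT
sublayer-thickness study in ABCA4-associated Stargardt disease (STGD1):
ETDRS-grid thickness extraction from segmented macular volumes, a
repeated-measures limits-of-agreement procedure for measurement
comparison, and a 33-model mixed-effects comparison of baseline
thickness and rate of change between STGD1 patients and controls. This
note records the models, the numerical choices, and what the synthetic
cohort generator does and does not emulate.

## ETDRS subfield thickness extraction

A segmented volume is a stack of 11 boundary surfaces (internal limiting
membrane to the outer boundary of the RPE/Bruch's complex) over a
B-scan × A-scan grid with physical pixel spacings and a fovea position.
Per-pixel sublayer thickness is the depth difference between consecutive
surfaces; the two outer-segment sub-bands are merged into a single OS
layer, giving 9 analyzed sublayers (NFL, GCL, IPL, INL, OPL, ONL, EZ,
OS, RPE). Two combined layers summarize the inner retina (NFL–OPL) and
outer retina (ONL–OS).

Subfield membership uses the Euclidean distance of each pixel *center*
from the fovea, in millimetres, with anisotropic spacing (mm per B-scan
differs from mm per A-scan). Boundaries are half-open: r ≤ 0.5 mm is the
center; 0.5 < r ≤ 1.5 mm the inner ring; 1.5 < r ≤ 3.0 mm the outer
ring — concentric zones with no double counting. The subfield value is
the unweighted mean over valid member pixels (no area weighting of edge
pixels; the brute-force test oracle applies the identical rule). A
subfield is reported as missing when the valid-pixel area falls below
`min_coverage_fraction` (default 0.9) of the subfield's analytic area —
truncated or poorly segmented scans yield missing values rather than
extrapolated means. Crossing surfaces are an error naming the offending
pixel and surface pair, never silently clipped.

## Mixed-model engine

All inference rests on an in-repo REML fitter for Gaussian linear mixed
models with nested grouping (patients; eyes within patients). Two
structures are used:

* **Nested random intercepts** (agreement models): a scalar intercept
  variance at each level plus a residual.
* **Nested intercept + slope** (longitudinal model): an unstructured
  2×2 covariance of intercept and years-slope at each level, i.e. the
  model `thickness ~ years + group + years:group` with random
  `~ 1 + years` per patient and per eye, intercept–slope correlation
  free at both levels.

A single-level random-intercept structure is also available for designs
without an eye level (it makes the balanced one-way closed-form REML
estimators directly expressible).

Estimation profiles the fixed effects (GLS) and the residual variance
out of the restricted likelihood and optimizes the remaining relative
covariance parameters on a log-SD / log-Cholesky scale, which enforces
positive semidefiniteness and makes zero-variance fits boundary events
(flagged, not errors) rather than negative estimates. The criterion and
its analytic gradient (envelope theorem: only the explicit dependence on
the covariance parameters survives at the profiled optimum) are
evaluated cluster-by-cluster with batched linear algebra over clusters
of identical shape; this keeps a bootstrap refit under ~10 ms at
realistic cohort sizes.

The REML surface is flat once variances approach zero, and a single
quasi-Newton descent from an arbitrary start can stall on that boundary.
The optimizer therefore ranks coarse start candidates by criterion
value, runs bounded L-BFGS-B (max 100 outer iterations, relative
tolerance 1e-10) from the best ones, and polishes with a short simplex
search; bootstrap refits instead warm-start from the full-data optimum.
Convergence and boundary status are carried on every fit; non-converged
fits are flagged, never silently reported.

Wald t-tests use containment ("inner–outer") denominator degrees of
freedom: a term is tested at the innermost grouping level at which it
varies (group: between patients, n_pat − 1 − p₁; laterality: between
eyes; years and years×group: observation level, N − n_eyes − p₃). The
intercept is tested at the observation level and excluded from the
per-level term tallies, matching the convention of the standard nested
ANOVA bookkeeping. Satterthwaite approximations are out of scope; small
p-value differences against software using other df rules are expected.

Cross-checks: the nested-intercept fits agree with statsmodels MixedLM
(variance-component formulation) to ~1e-6 in restricted log-likelihood;
the intercept+slope fits agree with R nlme's `lme` on identical data,
with our optimum never worse (nlme's `optim` search stops less tightly).
These fitters serve only as test oracles.

## Limits of agreement

For a source comparison (uncorrected segmentation minus grader average,
or grader A minus grader B), one difference per (eye, visit, layer,
subfield) is modeled twice with nested random intercepts: an
intercept-only model supplies the mean bias μ; a second model adds a
fixed years-since-baseline term and supplies the variance components.
The 95% limits are μ ± 1.96·√(σ²_patient + σ²_eye + σ²_residual), with
1.96 fixed (not configurable). When years has no variation (single visit
per eye) the years term is dropped as collinear, and the procedure
reduces exactly to classic Bland–Altman mean ± 1.96·SD.

Confidence intervals for the bias and both limits come from a stratified
cluster bootstrap (default 1999 replicates): strata are the distinct
numbers of scans per patient (a patient with two eyes × two visits sits
in stratum 4; a per-eye-visits stratification is available), patients
are resampled with replacement within each stratum preserving its size,
and redrawn patients are relabeled as fresh clusters (standard cluster
bootstrap). Both models are refit per replicate; CI bounds are the
empirical 2.5%/97.5% quantiles (type-7 interpolation) over converged
replicates. Non-converged replicates are dropped and counted — more than
5% triggers a warning, all failing is an error.

## Longitudinal analysis

Each of the 9 sublayers and 2 combined layers is modeled per subfield
(27 + 6 = 33 models) with the intercept+slope structure above, on the
grader-averaged records. The main model follows the formula
`thickness ~ years + group + years:group`; an OD/OS laterality term is
available behind a flag (and group means can be reported either at the
OD reference or averaged over laterality), since reasonable analyses
differ here. Group coding: control is the reference; baseline group
means and yearly rates with SEs come from fixed-effect contrasts, CIs
are estimate ± 1.96·SE. Years since baseline is computed per eye from
that eye's own baseline scan (scans are registered per eye).

Significance is Bonferroni-controlled at α = 0.05 over m = 33 tests
(threshold 0.05/33 ≈ 0.0015; displayed rounded to 4 decimals, full
precision internally). Rows that fail to converge or lack data appear
flagged rather than dropped, so m is preserved. Display rounding:
thickness and SE to 1 decimal, p to 3 decimals with a "< 0.001" floor.

## Synthetic cohort generator

The generator inverts the longitudinal model. Defaults are the study
conditions: 40 control and 63 STGD1 patients; each patient contributes
both eyes with probability 0.45 (the pooled both-eyes fraction of the
study cohort; the study's group-specific rates differ, which a single
probability cannot express); two scans per eye, baseline plus a
follow-up at an interval drawn uniformly from 1.2–8.2 years (the
distribution is unstated in the source; uniform is the least-assumption
choice and configurable). Patients with one eye get OD or OS with equal
probability. A config flag allows >2 visits solely to exercise the
bootstrap's visit-count strata.

Fixed effects default to the published cohort's baseline profile
(per-layer × subfield control means and group differences, e.g. ONL
center 116.9 µm control vs −92.9 µm difference). Control slopes default
to 0; STGD1 rate differences are chosen once to reproduce the published
aggregate rates — outer-retina thinning of about −3 µm/yr split as ONL
−2.0, EZ −0.3, OS −0.7, plus a small INL +0.2 µm/yr reflecting the
reported slight inner-retinal thickening — and are not tuned further.

Random effects: bivariate normal (intercept, slope) pairs per patient
and per eye, independent across layer × subfield combinations, with SDs
(8, 0.6) µm at the patient level, (3, 0.3) µm at the eye level, and
correlations defaulting to 0 (all configurable). The measurement model
emits three rows per scan value: a scan-level deviation (SD 2.5 µm,
shared by every source measuring that scan — it feeds the longitudinal
residual and cancels in between-source differences), independent grader
noise (SD 1.5 µm) for graders A and B, and an uncorrected row with
layer-specific bias (negative for GCL–INL, positive for ONL–RPE, largest
for the ONL) plus its own noise (SD 3 µm). Analysis of grader-averaged
data therefore sees a residual variance of sd_residual² + sd_grader²/2.

What the generator does **not** emulate: raw reflectance images or fleck
pathology; layer-dependent variance scales (a single global set of
variance SDs is used although the published SEs imply between-patient
SDs from ~4 to ~13 µm depending on the layer — very thin central layers
can therefore occasionally simulate negative thicknesses, which the
continuous-response models tolerate); cross-layer correlation of random
effects; group-specific eye-count rates; non-linear trajectories;
missingness beyond the Bernoulli single-eye draw. Passing tests
demonstrate correct recovery of the assumed hierarchical linear model,
not robustness to these real-data features.

The surface-fixture generator builds 11 cumulative surfaces from
per-sublayer radial thickness profiles (constants or radial step
functions), so surfaces never cross by construction, and emits the
grid-discretized expected subfield means alongside for testing.

## Known limitations and honest failures

* With two scans per eye, the eye-level slope variance is weakly
  identified: its REML estimate lands on the zero boundary in roughly a
  sixth of study-sized cohorts and its sampling distribution is heavily
  right-skewed, giving a median bias of about −15 to −25% at the default
  generating value (0.09 µm²/yr²). R nlme produces pairwise-matching
  estimates on identical cohorts, so this is a property of the estimator
  under this design, not of the implementation. The parameter-recovery
  test asserts a <10% median-bias bound for every component and is
  expected to fail on this one; all other components recover within ~6%.
* The containment df rule reproduces the nested-ANOVA convention but is
  one of several defensible choices; p-values near a significance
  boundary can differ from software using Satterthwaite df.
* Bootstrap CIs are percentile intervals; no BCa correction is applied.

## Problem sizes used in the test suite

Simulation studies in the test suite are scaled to what the scientific
check needs: parameter recovery uses 200 study-sized single-layer
cohorts; bootstrap coverage uses 100 cohorts of 25 patients with 499
replicates; family-wise error uses 60 null runs of 30 patients across
the full 33-model plan; the cross-implementation oracles use 20
(statsmodels) and 3 (nlme) seeded datasets. The acceptance script runs
one full study-sized cohort through the entire pipeline with 499
bootstrap replicates.
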