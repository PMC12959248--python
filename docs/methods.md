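# Methods

## Problem and scope

`melmorph` measures objective morphological biomarkers of invasive melanoma
from a binary whole-slide segmentation mask and evaluates their prognostic
value against overall survival (OS) and melanoma-specific survival (MSS).
The segmentation itself (a two-class CNN labelling each pixel invasive
melanoma / not) is upstream and out of scope: the package consumes its
binary output plus a microns-per-pixel calibration.

Five biomarkers are derived from the **largest 8-connected piece** of
segmented tumour (restricting to the largest piece makes the measurement
insensitive to serially sliced specimens with several tumour-bearing
sections on one slide):

| biomarker | definition | units |
|---|---|---|
| area *A* | foreground pixel count × pixel area | mm² |
| perimeter *P* | length of the sub-pixel outer contour | mm |
| major axis *L* | long side of the minimum-area enclosing rectangle | mm |
| digital Breslow thickness (dBT) | short side of the same rectangle | mm |
| Nodularity Index (NI) | dBT / *L* ∈ (0, 1] | — |

NI is size-free: it measures tumour depth per unit width ("nodularity"),
with 1 = maximally nodular. dBT is so named because the rectangle's short
side rank-correlates strongly with pathologist-measured Breslow thickness.

## Geometry

**Coordinates.** Pixel (i, j) has its centre at
((j + 0.5)·mpp_x, (i + 0.5)·mpp_y)/1000 mm, y downward. Anisotropic pixels
are supported; all geometry happens after conversion to isotropic mm.

**Components.** 8-connectivity (diagonal contact joins), labelled in
row-major scan order; "largest" means largest physical area, ties broken by
scan order. Enclosed holes are background: they count toward neither area
nor perimeter (the perimeter is the outer boundary only).

**Contour and perimeter.** The outer boundary is traced by marching squares
at the 0.5 iso-level on the zero-padded component (diagonally connected
foreground, matching 8-connectivity). The raw iso-contour is a 45°
staircase whose length overestimates a smooth boundary by ≈5% *independent
of resolution* (the staircase never converges in length), so the contour is
simplified by Douglas–Peucker at a one-pixel tolerance before measuring.
Simplification runs in pixel-index space so the result is exactly
equivariant under calibration changes. With this estimator, disc and
ellipse perimeters converge to the analytic values within 1–2% at
mpp ≤ 0.02 mm. Very small components whose simplified contour would
degenerate keep the raw contour.

**Bounding rectangle.** The minimum-**area** enclosing rectangle of the
contour's convex hull, computed by rotating calipers: the optimum has one
side flush with a hull edge, so evaluating the axis-aligned box in each
edge frame suffices. Ties go to the smallest orientation angle (reported
folded to [0, 90), a rectangle's canonical form). A dense 0.01° rotation
sweep serves as the independent oracle in the tests (area agreement to
1e-4 relative); shapely's `minimum_rotated_rectangle` is never used in the
computation path. The minimum-perimeter or width-based rectangle would be
alternative readings of "bounding box"; minimum-area is the canonical
rotating-calipers product and the per-case angle is retained for audit.

**Numerical edge cases.** Empty masks raise a distinct "no tumour" error
(a countable outcome, not an I/O failure); collinear geometry raises a
degenerate-geometry error; a single pixel still yields a valid positive-area
contour.

## Survival workflow

Given a cohort table (biomarkers + age, sex, site + OS/MSS endpoints) the
workflow runs, in order:

1. **Quartile Kaplan–Meier.** Each biomarker is split at its sample
   quartiles (type-7 quantiles; boundary ties to the lower group, all-equal
   input is an error), curves per quartile, k-sample log-rank test.
2. **Cox proportional hazards**, one model per biomarker per endpoint,
   unadjusted and adjusted for age (continuous years by default; a ≥50
   indicator is available), sex (male vs female) and site (central vs
   peripheral). Biomarkers enter as natural logs (they are right-skewed;
   NI ≤ 1 so log NI ≤ 0, which is fine — only strict positivity is
   required, and zero/negative values are a hard error listing case ids).
   Ties: Efron. Missing covariates: complete-case per model with the drop
   count reported. Hazard ratios with Wald 95% CIs are primary; a
   non-parametric case-resampling bootstrap (percentile CI, default
   B = 1000 when invoked, failed replicates dropped and counted, >10%
   failures is an error) is available per model. The full-report default is
   B = 0 because bootstrapping all 20 models is a dedicated call at desk
   scale.
3. **Harrell's C** of each model's linear predictor. Implemented by
   definition: usable pairs are those whose shorter observed time carries an
   event; tied scores count ½; tied times with two events are unusable.
   The O(n²) enumeration is vectorized; a literal pair loop is the test
   oracle.
4. **Schoenfeld residual PH checks** per adjusted model (rank-transformed
   event times). Per-covariate chi-square tests come from lifelines; the
   "global" value sums the per-covariate statistics with df = k — an
   approximate omnibus that ignores cross-covariate correlation (adequate
   as a screen; the per-covariate tests are the primary diagnostic).
5. **5-year logistic/ROC comparison** for melanoma-specific death:
   predictor sets {Breslow}, {dBT}, {NI}, {dBT, NI}, {AJCC}, {AJCC, NI}
   (whichever columns exist). Subjects censored alive before 5 years have
   unknown 5-year status and are excluded, with the count reported. AUC is
   the trapezoid under the empirical ROC, which equals the Mann–Whitney
   statistic. Complete separation is an error; constant predictors fall
   back to the intercept-only model (AUC 0.5).
6. **Spearman collinearity screen** over age/sex/site and **Wilcoxon
   rank-sum subgroup contrasts** of each biomarker against the binary
   clinical features present (exact enumeration when both groups ≤ 10 and
   tie-free, else normal approximation with tie correction).

All p-values are raw; the family-wise threshold p ≤ 0.001 only flags.
The whole workflow is exposed as `MelanomaSurvivalModel(...).fit()` →
`MelanomaSurvivalResults` (summary table, JSON report, KM/ROC plots).

## Synthetic data

The study's WSIs and cohort are not public, so the generator reproduces
their documented structure; it is what the tests and the acceptance checks
run against.

**Shapes.** Ellipses (optionally rotated), nodular blobs (near-circular
with a smooth periodic radial perturbation, amplitude ≤ 0.2), superficial
strips (high aspect ratio) and fragmented lesions (satellite discs, each
< 50% of the main area, spread at distinct angles). Ground truth is
analytic for zero noise: area πab, axes 2a/2b, NI b/a, perimeter from the
complete elliptic integral.

**Cohorts.** Per case:

* Biomarkers + gold-standard Breslow: log-normal marginals coupled by a
  Gaussian copula. The latent correlation is 2·sin(πρ/6) of the target
  Spearman matrix, whose dBT↔Breslow entry is 0.89. Marginal medians
  (area 10 mm², perimeter 20 mm, major 8 mm, dBT 2.2 mm, NI 0.28,
  Breslow 2.0 mm) and log-SDs (0.90/0.55/0.50/0.65/0.45/0.60) describe a
  mixed superficial-spreading/nodular case mix; the Breslow marginal
  reproduces the reported ≤1 / 1–2 / 2–4 / >4 mm band fractions to within
  a few percent. NI is clipped at 1 (it is a ratio ≤ 1 by definition;
  < 0.3% of draws are affected).
* Covariates: age ~ Normal(μ, 15) clipped to [18, 95] with μ solved so
  P(age ≥ 50) = 0.76; sex and site Bernoulli(0.5), independent of the
  biomarkers.
* Survival: one **designated** biomarker drives a Weibull
  proportional-hazards death time (shape 1.1), linear predictor
  β·(log x − μ) + β_age(age − 60) + β_sex·male + β_site·central. The
  designated β defaults to the published adjusted hazard ratio for that
  biomarker and endpoint (OS: 1.48 area, 1.86 perimeter, 1.88 major,
  1.77 NI, 2.04 dBT; MSS: 2.34 NI, 2.59 dBT; MSS values for
  area/perimeter/major are not published and default to the OS value scaled
  by the dBT MSS/OS log-ratio). Nuisance defaults (age HR 1.03/year, male
  1.3, central 1.2) are plausible, explicitly non-reference values.
* Cause of death: each death is melanoma-caused with probability 0.75;
  MSS censors other-cause deaths at the death time. Because one latent time
  drives both endpoints, the designated β is the cause-specific coefficient
  for both — the designated *endpoint* only selects which coefficient table
  supplies it.
* Censoring: C = 33.7·U^p (right-skewed power-of-uniform, maximum 33.7
  years). A uniform window cannot simultaneously reproduce a 5.7-year
  median follow-up, a 33.7-year maximum and 30% deaths, which is why the
  skewed family is used. The Weibull baseline scale and the power p are
  solved by nested bisection *on the realized draws* so each generated
  cohort's observed death fraction and median follow-up (simple median of
  observed times) hit 0.30 and 5.7 y essentially exactly; the calibration
  is part of the generator, not post-hoc tuning.

**What the generator does not emulate:** geometric consistency between a
case's biomarker columns (they are copula draws, not measured from a common
mask); accrual-time trends; centre effects across the five source cohorts;
covariate–biomarker dependence (subgroup differences by age/sex exist in
the real data but are not built in); informative censoring. Passing tests
therefore demonstrate that the *estimation machinery* is correct and that
effects of the published size are recoverable at the published censoring
structure — not that the published clinical estimates are externally valid.

## Problem sizes and tolerances

Default cohort n = 2000 with the default seed 20260304. Recovery checks
fit the adjusted Cox model on 50 seeds per designated biomarker and require
the generating hazard ratio inside the fitted 95% CI in ≥ 90% of seeds;
the family-wise null check uses 40 all-β=0 cohorts and requires no
biomarker at p ≤ 0.001 in ≥ 95% of them. Geometry fixtures use
mpp 0.08→0.02 mm for convergence and 0.01 mm for rotation invariance;
the rectangle oracle sweeps 0.01° steps. Bootstrap calibration runs at a
reduced nested scale (n = 120, B = 120, 30 outer replicates). These sizes
are the package's desk-scale defaults; every one is a parameter.

## Known limitations

* The perimeter depends mildly on the simplification tolerance (one pixel);
  alternative perimeter estimators (e.g. Crofton) would differ at the
  sub-percent level.
* The approximate global Schoenfeld statistic is conservative/liberal
  depending on covariate correlation; use the per-covariate tests for
  decisions.
* The 5-year logistic analysis discards subjects censored alive before
  5 years rather than weighting them (IPCW), matching the simplest reading
  of the original analysis; with heavy early censoring this can bias AUC
  comparisons.
* Multi-biomarker Cox models, competing-risks (Fine–Gray) and flexible
  parametric survival models are deliberately out of scope.
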