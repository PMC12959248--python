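# melmorph

Objective morphometric biomarkers of invasive melanoma from whole-slide
segmentation masks, and the complete survival-analysis workflow that
evaluates them.

Breslow thickness — the depth of dermal invasion in mm — has been the
dominant prognostic biomarker in melanoma for half a century, yet it is
measured by hand and subject to marked inter-observer variation. Given a
binary segmentation of invasive melanoma in a whole-slide image (e.g. the
output of a segmentation CNN) plus its microns-per-pixel calibration,
`melmorph` derives five objective parameters of tumour size and shape from
the **largest connected piece** of tumour and evaluates each against overall
survival (OS) and melanoma-specific survival (MSS):

* **area** *A* (mm²) and **perimeter** *P* (mm) of the tumour outline;
* **major axis length** *L* and **digital Breslow thickness** (dBT) —
  the long and short side of the *minimum-area enclosing rectangle* of the
  tumour, found by rotating calipers over the convex hull;
* **Nodularity Index** NI = dBT / *L* ∈ (0, 1] — a size-independent shape
  metric (tumour depth per unit width; 1 = maximally nodular).

The evaluation follows the standard biomarker-discovery workflow: quartile
Kaplan–Meier curves with log-rank tests; Cox proportional-hazards models of
each log-transformed parameter, unadjusted and adjusted for age, sex and
anatomical site, HR = exp(β) with Wald 95% CI and optional case-resampling
bootstrap; Harrell's concordance index; Schoenfeld-residual checks of the
proportional-hazards assumption; logistic/ROC comparison for
melanoma-specific death at 5 years; Spearman collinearity screens and
Wilcoxon rank-sum subgroup contrasts. A family-wise threshold of p ≤ 0.001
is flagged throughout (p-values are always reported raw).

Because the clinical whole-slide images and cohort behind this design are
not public, the package ships a first-class synthetic module: tumour-shaped
masks with analytically known geometry, and survival cohorts with the
documented statistical structure (log-normal biomarkers under a Gaussian
copula with dBT↔Breslow rank correlation 0.89; Weibull
proportional-hazards times whose generating hazard ratios default to the
published adjusted estimates; censoring calibrated to a 5.7-year median
follow-up, 33.7-year maximum and 30% deaths). See `docs/methods.md`.

## Worked example

Measure a synthetic elliptical tumour (semi-axes 12 × 4 mm, rotated 25°,
rasterized at 0.02 mm/px):

```python
from melmorph import SyntheticShapeSpec, generate_shape, compute_morphometrics

mask, truth = generate_shape(SyntheticShapeSpec(a=12, b=4, rotation=25,
                                                mpp=0.02, seed=1))
rec = compute_morphometrics(mask)
print(f"area {rec.area:.2f} mm^2   perimeter {rec.perimeter:.2f} mm")
print(f"major {rec.major_axis:.2f} mm   dBT {rec.minor_axis:.2f} mm   "
      f"NI {rec.nodularity_index:.3f}")
```

```
area 150.80 mm^2   perimeter 53.49 mm
major 24.01 mm   dBT 8.02 mm   NI 0.334
```

The analytic values are πab = 150.80 mm², perimeter 53.46 mm, axes
24 × 8 mm, NI = 1/3: every measurement is within 0.1–0.3% at this
resolution. Evaluate the biomarkers on a synthetic cohort (2000 cases,
dBT designated as the hazard-driving parameter with generating HR 2.04):

```python
from melmorph import SyntheticCohortSpec, generate_cohort, MelanomaSurvivalModel

cohort, _ = generate_cohort(SyntheticCohortSpec(seed=42))
results = MelanomaSurvivalModel(cohort).fit()
print(results.summary())
```

```
parameter endpoint model           HR           95% CI          p      C
...
dbt       OS       unadjusted    2.06      (1.81-2.34)   1.16e-28  0.628 *
dbt       OS       adjusted      2.05      (1.81-2.33)   6.22e-29  0.673 *
...
5-year melanoma-specific survival (logistic/ROC):
  breslow                AUC 0.600  (n=1259, events=203, excluded=741)
  dbt                    AUC 0.628  (n=1259, events=203, excluded=741)
  ni                     AUC 0.554  (n=1259, events=203, excluded=741)
  dbt+ni                 AUC 0.632  (n=1259, events=203, excluded=741)
```

The adjusted dBT model recovers the generating hazard ratio (2.05 vs 2.04)
with the generating value inside the Wald CI; the starred rows meet the
family-wise p ≤ 0.001 threshold. `results.to_json()`, `results.plot_km()`
and `results.plot_roc()` export the full report and figures.

The same workflow is available from the shell:

```bash
melmorph simulate --out fixtures --seed 1          # masks + cohort fixtures
melmorph morph fixtures/masks --mpp 50 --out morph.csv
melmorph survival --cohort fixtures/cohort.csv --out report/
melmorph all --mode synthetic --out report/        # end to end
```

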