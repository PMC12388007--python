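# metavol

Quantitative FDG-PET biomarkers and prognostic stratification for lymphoma
cohorts.

In diffuse large B-cell lymphoma (DLBCL), baseline ¹⁸F-FDG PET/CT carries
prognostic information beyond clinical indices: the volumetric tumor burden,
how heterogeneous the uptake is inside the lesion, and even the uptake of
normal liver tissue have all been linked to survival. `metavol` implements
this biomarker stack end to end for imaging scientists and clinical
statisticians:

* **lesion quantification** from a SUV volume and ROI masks — SUVmax,
  SUVmean, SUV SD, SUVpeak (mean over a 1 mL sphere at the hottest voxel),
  metabolic tumor volume at absolute SUV thresholds, total lesion
  glycolysis, and liver-reference SUVmax/SUVmean;
* **heterogeneity indices** — HI1, the intratumoral coefficient of
  variation SD(SUV)/SUVmean, and HI2, the negative slope of the ordinary
  least-squares line through the (threshold, MTV) points. For the default
  thresholds (2.5, 3.0, 3.5),

  HI2 = −slope = MTV(2.5) − MTV(3.5)   [mL per SUV unit];

* **prognostic statistics** — Kaplan–Meier curves with restricted mean
  survival ± SE, Mantel–Cox log-rank tests, empirical ROC curves with
  Youden-index cutoffs (J = sensitivity + specificity − 1), logistic
  regression with Wald odds-ratio CIs, chi-square/Fisher and Mann–Whitney
  comparisons gated by a Lilliefors normality test;
* **synthetic ground truth** — ellipsoidal digital phantoms whose radially
  linear uptake profile gives *closed-form* MTV(T) = V·r*³ with
  r* = clamp((SUVcore − T)/(SUVcore − SUVrim), 0, 1), and cohort simulation
  with an explicit logistic outcome model on dichotomized markers, so every
  estimator in the package can be checked against an analytic answer.

The cohort stage follows the statsmodels idiom: `CohortAnalysis(df,
config).fit()` returns a results object carrying the summary, ROC,
Kaplan–Meier and logistic tables.

## Worked example

```python
from metavol import (PhantomSpec, generate_phantom, quantify_lesion,
                     CohortGenParams, generate_cohort, CohortAnalysis)

# a 20 mm graded lesion (core SUV 4.5, rim 1.0) on a 2 mm grid
vol, lesion, liver, truth = generate_phantom(PhantomSpec())
m = quantify_lesion(vol, lesion, liver)
print(m.mtv_ml, m.hi2, truth.analytic_hi2)

# a 300-patient synthetic cohort with marker-driven mortality
df, _ = generate_cohort(CohortGenParams(n=300, seed=1))
res = CohortAnalysis(df).fit()
print(res.summary())
```

The quantification step prints

```
SUVmax 4.50  SUVmean 1.88  SUVpeak 3.69  HI1 0.360
MTV profile (mL): {2.5: 6.01, 3.0: 2.73, 3.5: 0.74}
HI2 5.26 mL/SUV   (analytic 5.47)
liver SUVmax 2.3
```

— the voxelized MTV profile sits within one voxel-shell of the closed form
(analytic MTV(2.5) = 6.25 mL), and HI2 approaches the analytic 5.47 as the
grid is refined. The cohort analysis reports, among other tables,

```
    variable cutoff        model  odds_ratio  ci_low  ci_high     p
suvmax_liver  <= 22   univariate       5.294   3.006    9.325 0.000
         hi2 > 62.3   univariate       5.521   2.839   10.737 0.000
 ldh_u_per_l  > 301   univariate       0.852   0.519    1.397 0.525
suvmax_liver  <= 22 multivariate       5.944   3.272   10.798 0.000
         hi2 > 62.3 multivariate       6.319   3.138   12.725 0.000
```

reading as: patients with liver SUVmax ≤ 22 or HI2 > 62.3 carry a five- to
six-fold mortality odds in this simulated cohort (the generating model put
effects on exactly those indicators; LDH was given no death effect and
correctly comes out null).

A command-line interface mirrors the library: `metavol simulate`,
`metavol quantify --volume v.nii.gz --lesion l.nii.gz --liver h.nii.gz`,
`metavol analyze --cohort cohort.csv --out report/`, and
`metavol fixtures --table demographics` (packaged reference aggregate
tables).

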