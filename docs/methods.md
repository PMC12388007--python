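# Methods

This note documents the quantitative conventions `metavol` implements, the
defaults it ships, what the synthetic generators do and do not emulate, and
the design choices made where the underlying definitions are genuinely open.

## SUV quantification

A standardized uptake value is the tissue activity concentration normalized
by injected dose per body weight: SUV = C [kBq/mL] · weight [kg] / dose
[MBq], assuming the dose is decay-corrected to scan time and 1 kg of tissue
occupies ~1 L. `compute_suv` is linear in activity and inversely
proportional to dose by construction.

Region statistics use voxel-centre membership on a (z, y, x) grid with
world position `origin + index · spacing` (mm). Conventions that matter and
their rationale:

* **SUV SD** is the sample standard deviation (n−1). This is the SPSS
  default, the software lineage of most clinical PET reports; a singleton
  region has SD 0 by convention.
* **SUVpeak** is the mean over voxels whose centres lie within a sphere of
  1 mL (radius 6.2035 mm) centred on the hottest masked voxel — the
  EANM-style "volumetric method". The sphere may leave the mask but is
  clipped at the grid. Hot-voxel ties break to the lowest (z, y, x) index,
  making the result deterministic. The sphere volume is a parameter.
* **MTV** uses absolute SUV thresholds (defaults 2.5 / 3.0 / 3.5, the
  common triple for lymphoma), with an *inclusive* comparison (SUV ≥ T):
  a voxel exactly at threshold belongs to the metabolic volume, so the
  threshold isosurface is never dropped. MTV in mL is the voxel count times
  the voxel volume (product of spacings / 1000). Across multiple lesions,
  MTV is the sum over the union mask.
* **TLG** is the mean SUV over the threshold-segmented voxels times the
  MTV at that threshold; 0 for an empty segmentation.
* Uptake values are treated as abstract units throughout: every cutoff in
  the prognostic stage is configuration, because the absolute scale of a
  cohort's SUVs depends on the acquisition and reconstruction pipeline.

NIfTI-1 is the interchange format; only axis-aligned (diagonal-affine)
volumes are accepted, since voxel-volume arithmetic on an oblique grid
would silently be wrong.

## Heterogeneity indices

HI1 = SD(SUV)/SUVmean is computed over the *full* lesion mask, not a
threshold-restricted subvolume (the definition refers to the lesion's SUV
distribution without restriction); it is dimensionless and invariant to
voxel spacing and to uniform rescaling of uptake.

HI2 is the negative slope of the unweighted OLS line through the
(threshold, MTV) points — with three points there is nothing to weight by.
For equally spaced thresholds t₁ < t₂ < t₃ the centred cross-product form
of the slope gives HI2 = MTV(t₁) − MTV(t₃) exactly, independent of the
middle point; this identity is the package's main internal oracle. Units
are mL per SUV unit; values are reported unclamped (a noisy non-monotone
profile can give a small negative HI2; clamping would bias downstream ROC
cutoffs).

## Digital phantoms

Phantoms place one or more ellipsoidal lesions with a radially linear
profile suv(r) = SUVcore + (SUVrim − SUVcore)·r at normalized ellipsoidal
radius r ∈ [0, 1], a uniform liver reference ellipsoid, and a uniform
background in a rectangular grid. The linear profile is chosen precisely
because it admits a closed-form MTV(T) = V·r*³ with
r* = clamp((SUVcore − T)/(SUVcore − SUVrim), 0, 1), giving an analytic
target that real images never provide. Noise is additive Gaussian on SUV
(the phantom imitates a *reconstructed* image, not raw counts) with values
clipped at 0, reproducible from the seed.

What the phantom does **not** emulate: scanner physics, attenuation,
scatter, partial-volume blur, reconstruction artefacts, correlated noise,
or irregular lesion shapes. Agreement between voxelized and analytic MTV
therefore validates the *segmentation arithmetic* (tested to shrink within
a one-voxel shell on the threshold isosurface at 4 → 2 → 1 mm spacing),
not robustness to real-image degradation.

## Synthetic cohorts

The generator draws covariates from distributions chosen once to resemble
an aggressive B-cell lymphoma population: age ≈ N(60, 13) clipped to
26–89; 58.6% male; stage distribution (20, 13, 17, 50)%; LDH log-normal
with median 300 U/L; liver SUVmax ≈ N(22, 5) rounded to integers (as such
values are reported clinically); HI2 log-normal with median 90 and log-SD
1.4 so that meaningful mass falls on both sides of the 62.3 and 87.9
cutoffs; blood counts built as neutrophils + lymphocytes + other so the
count invariants hold by construction. Per-patient MTV profiles are
monotone non-increasing and satisfy HI2 = MTV(2.5) − MTV(3.5) exactly.

Outcomes come from explicit logistic models on the *dichotomized* markers
(liver SUVmax ≤ 22, HI2 > 62.3, LDH > 301 for death; the analogous set
with HI2 > 87.9 and liver SUVmax ≤ 21 for relapse). Default coefficients
are the log odds ratios the markers are designed to carry (log 8 for low
liver SUVmax on death, etc.); intercepts are set so the marginal event
rates land near 30% (death) and ~42% (relapse), the rates typical of such
cohorts. Event times are exponential with rate
`baseline_hazard · exp(marker effects)` (default 0.005/month), truncated
at the administrative horizon (96 months) for subjects whose indicator
fired; event-free subjects are censored uniformly on (3, horizon) months,
and relapse-free time is capped at overall survival time. Because the
event *indicator* is exactly the logistic draw, a downstream logistic fit
is an unbiased estimate of the generating coefficients — this is what the
parameter-recovery and null-calibration tests exploit. The price is mild
artificiality: the time-to-event and event-indicator models are linked
only through a shared linear predictor, not a single coherent hazard
model, and censoring is purely administrative (uniform), since no
follow-up distribution was available to copy.

The margin-matched 70-patient reference cohort (`reference_cohort`) is
deterministic: categorical margins are allocated independently inside the
deceased (21) and surviving (49) strata, which reproduces the packaged
demographic percentages exactly and the joint cells that link relapse,
response and mortality (all deceased relapsed; 8 survivors relapsed; 19 of
21 deceased responded). Its continuous values are fillers; only the
margins are meaningful.

## Survival and regression conventions

* **Kaplan–Meier**: product-limit estimate (via lifelines) with Greenwood
  variance; censoring tied to an event time counts as censored after the
  event.
* **Mean survival** is the *restricted* mean — the area under the KM curve
  up to the largest observed time (SPSS's "mean survival time") — with the
  classic variance Σ A_j² d_j / (n_j (n_j − d_j)), A_j the area under the
  curve after the j-th event time; a term with A_j = 0 contributes nothing
  (so a single subject has SE 0). 95% intervals are mean ± 1.96·SE; z =
  1.96 is used everywhere in the package.
* **Log-rank** is the Mantel–Cox statistic with k − 1 df.
* **ROC cutoffs**: candidate cutoffs are midpoints between consecutive
  distinct scores; the reported cutoff maximizes Youden's J, ties breaking
  toward the cutoff that classifies fewer subjects positive (a
  deterministic and conservative choice). Markers where *low* values
  predict the event use `direction="low_positive"`, which negates scores
  internally; the cutoff is then read as "positive when ≤ cutoff". The AUC
  is trapezoidal and equals U/(n₁n₂), an identity the tests assert across
  modules.
* **Logistic regression** is Newton maximum likelihood (statsmodels) with
  Wald CIs exp(β ± 1.96·SE) and Wald p-values. Complete separation is
  flagged as non-convergence (|β| > 15 or exploding SEs) rather than
  reported as a huge finite OR. On a saturated binary model the MLE equals
  the 2×2 cross-product ratio ad/bc, the package's second cross-module
  identity. Zero-cell tables raise rather than receive a Haldane
  correction.
* **Categorical comparisons** use Pearson chi-square without continuity
  correction (this convention, not Yates', reproduces the reference
  treatment-response p = 0.028 exactly); Fisher's exact test is used when
  an expected cell count falls below 5.
* **Continuous comparisons** are routed by a Lilliefors
  (estimated-parameter KS) normality test: non-normal or degenerate
  samples go to Mann–Whitney U (mid-ranks, normal approximation with tie
  correction and no continuity correction; exact enumeration when
  n₁ + n₂ ≤ 12), normal ones to Student's t.
* **Dichotomization** is inclusive on the low side (low = value ≤ cutoff).
  Exposure indicators point in the event-predicting direction, so odds
  ratios are ≥ 1 for harmful marker states; a protective coding (OR below
  1 for the complementary indicator) is its exact reciprocal.
* **Multivariate model composition**: all markers univariately significant
  at α (default 0.05) for that endpoint enter jointly; overridable via the
  config. No multiple-testing adjustment is applied, matching the
  single-centre workflow the package mirrors.
* The pipeline never imputes: missing values shrink denominators
  (pairwise deletion), never become zeros.

## Inflammation-nutrition indices

Standard literature definitions: NLR = neutrophils/lymphocytes; dNLR =
neutrophils/(WBC − neutrophils); SII = platelets · neutrophils /
lymphocytes; PNI = 10 · albumin [g/dL] + 0.005 · lymphocytes [/mm³]. A
zero denominator yields a missing value, not an infinity. Note the
packaged reference table reports PNI on roughly one-tenth of this
conventional scale; the transcription stores the printed values verbatim
while `derive_indices` uses the standard formula.

## Problem sizes and determinism

Default test and acceptance problem sizes are chosen for tight oracles at
desk scale: phantoms at 4/2/1 mm spacing (up to ~3M voxels), simulated
cohorts of 150–5000 patients, 100-seed calibration loops. All generators
take explicit integer seeds (numpy `default_rng`); identical seeds give
byte-identical cohort CSVs and phantom volumes, and the analysis stage is
fully deterministic given its input.

## Known limitations

* Absolute-SUV thresholding only; %-of-SUVmax or adaptive segmentation
  conventions are not implemented (the threshold list is configurable).
* No texture/radiomics heterogeneity features; HI1/HI2 only.
* No Cox modelling or time-dependent ROC; the prognostic stage is the
  dichotomize → KM/log-rank → logistic workflow.
* The phantom's noise model is uncorrelated Gaussian; passing tests bound
  discretization error, not clinical robustness.
* The cohort generator's outcome model is marker-driven by design; it
  cannot be used to study confounding structures it does not contain.
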