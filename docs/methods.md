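# Methods

This note documents the models and procedures implemented in `wmhkit`,
the defaults and why they were chosen, the numerical decisions, and the
limits of what the synthetic data can demonstrate.

## WMH segmentation

The segmentation operates on a FLAIR-like volume and a brain (ICV) mask
assumed to live on one common voxel lattice; registration and
skull-stripping are upstream concerns. `compute_brain_mask` is a
deliberately simple stand-in — Otsu threshold on the (optionally fused)
image, largest connected component, hole fill — adequate for phantoms and
for roughly skull-stripped inputs, not a replacement for a dedicated
brain-extraction tool.

Stages, in order, each strictly subtractive after the first:

1. **Thresholding.** Keep in-brain voxels with intensity strictly above
   μ + k·σ, with μ, σ the mean and SD over the brain mask and k = 1.3.
   Strict inequality resolves ties at the cutoff: "above" means
   exceedance, and it makes the σ = 0 case (constant image) cleanly
   empty. The rule is scale-equivariant — rescaling intensities rescales
   μ and σ together — so no intensity normalization is needed here.
2. **Template removal** (optional). Voxels where a lesion-distribution
   template, valued in [0, 1], is ≤ `template_min` are removed. The
   default `template_min = 0` removes only locations the template
   declares impossible; raising it makes the prior stricter.
3. **Refinement.** In-brain intensities are min–max normalized to [0, 1]
   (the 0.1 floor is only meaningful on a normalized scale), smoothed
   with an isotropic Gaussian of `smooth_sigma_mm` (default 0.5 mm,
   converted to voxel units per axis — sub-voxel so that 2–3 mm lesions
   survive), and mask voxels are dropped when the smoothed value is
   below 0.1 or its z-score over brain voxels of the smoothed image is
   below 0.95. The z-score reference population is the brain mask: 0.95
   is then "just under one SD above the mean brain intensity", which is
   the natural reading of a z-floor applied after smoothing.
4. **Exclusion.** Set difference against any number of exclusion masks.
   This is how manually-delineated acute infarcts, old stroke lesions,
   and perihematomal edema are handled; the pipeline itself never adds
   voxels back (manual *additions* are out of scope — the pipeline is
   strictly subtractive after thresholding).
5. **Volumetrics.** Voxel counts × voxel volume; WMH reported as a
   percentage of ICV. WMH voxels outside the ICV mask are reported as a
   warning, not an error, because upstream mask edits can legitimately
   produce a few.

Degenerate inputs (constant images, empty brain masks, zero post-smoothing
variance) raise a dedicated error rather than returning an empty mask, so
silent upstream failures do not masquerade as lesion-free subjects.

## Lesion probability maps and voxel-wise inference

A probability map is the voxel-wise mean of n binary masks; its values
are exact multiples of 1/n by construction. Group comparison uses the
Wilcoxon rank-sum test on the per-subject 0/1 values at each voxel, with
midranks and tie correction, as a two-sided normal approximation; with
more than two groups the tie-corrected Kruskal–Wallis chi-square is used.
On binary data both statistics are closed-form functions of the per-group
lesion counts, so the whole grid is evaluated with array arithmetic; the
test suite checks the reduction against scipy and against an exhaustive
permutation oracle (all label assignments for n ≤ 12 per group, grouped
by hypergeometric symmetry for larger n). No continuity correction is
applied voxel-wise; the cohort-level Mann–Whitney applies one by default,
which is each convention's common default, and the cross-module
consistency test compares them with the correction switched off. The
normal approximation is justified by the intended group sizes (on the
order of 10² per group); at n ≲ 10 per group its p-values are only
qualitatively close to exact permutation values because the permutation
distribution is extremely discrete.

Voxels with zero variance across all subjects — in particular voxels
lesioned in nobody — get p = 1, and testing is restricted to an analysis
mask that defaults to the union of all masks. This keeps the
multiple-testing burden proportional to the lesioned footprint instead of
the grid. FDR control is Benjamini–Hochberg step-up (adjusted value for
rank i = min over j ≥ i of m·p(j)/j, capped at 1); BH rather than
Benjamini–Yekutieli because the positive-dependence structure of
neighbouring voxels is the canonical BH use case, and plain FDR is the
stated multiplicity standard of this analysis layer. Difference maps are
three-valued labels with asymmetric defaults (group A shown where its
lesion frequency is ≥ 0.75 and exceeds B; group B where ≥ 0.60 and
exceeds A), applied to raw per-voxel probabilities; the thresholds are
configurable.

Matched samples are built greedily: subjects of the smaller group, in a
seeded random order, each claim the best unclaimed partner that agrees
exactly on all categorical variables (default: sex plus the binary risk
factors) and lies within the caliper on continuous ones (default: age
within 5 years), minimizing the age distance, ties to the earlier row.
Greedy nearest-neighbour without replacement is not globally optimal, but
it is the standard, auditable choice, deterministic given seed and input
order; balance is verified with standardized mean differences (< 0.1 on
matched covariates in the tests). Infeasible subjects are reported
unmatched; a fully infeasible problem warns and returns an empty result
rather than raising.

## Cohort statistics

* **Chi-square** is Pearson's statistic without continuity correction on
  2×k count tables. This was validated against the published univariable
  p-value column recomputed from printed counts: the uncorrected
  statistic reproduces all twelve two-decimal-stable values (0.349,
  0.940, …) to three decimals, while Yates-corrected values do not.
* **Fisher's exact test** sums hypergeometric probabilities of all tables
  with the observed margins whose probability does not exceed the
  observed one (relative tie tolerance 1e−9). `fisher_p_by_margins`
  evaluates all tables sharing one margin set in a single pass; the test
  suite and acceptance script verify every 2×2 table with N ≤ 40 against
  a pure-factorial enumeration.
* **Test selection** follows the usual expected-count rule: Fisher when
  any expected cell is below 5 on a 2×2 table, chi-square otherwise.
  Which continuous variables get t versus Mann–Whitney is a caller
  decision; the built-in univariable table applies Welch t to age and
  rank tests to scores, counts and volumes.
* **Logistic models.** Model 1 regresses phenotype (dICH = 1, so OR > 1
  reads "more associated with dICH") on age, sex, vascular risk factors
  and pre-stroke medications. Model 2 keeps age, sex, the Model-1
  predictors with Wald p < 0.05 (threshold configurable), and adds the
  SVD markers: lacune presence, total WMH score, moderate-to-severe
  basal-ganglia PVS, CMB presence (complete cases only — subjects
  without a susceptibility sequence drop out of Model 2), and optionally
  log10-transformed WMH %ICV. Fitting is Newton/IRLS via statsmodels
  (tolerance 1e−8, 100 iterations), with quasi-perfect separation
  detected and flagged instead of silently diverging. Inference is Wald:
  OR = e^β with 95% CI e^{β ± 1.96·SE}; profile-likelihood intervals are
  not implemented because at the intended sample sizes (10³) the
  difference is negligible. Collinearity is screened with VIF = 1/(1−R²)
  per predictor, flagged above 5; exact collinearity reports an infinite
  VIF rather than an exception.
* **Cohen's kappa** uses marginal-product chance agreement. The
  degenerate case of two identical constant raters (chance agreement 1)
  is defined as κ = 1 with a warning, since observed agreement is
  perfect.
* **SVD derivations.** Total WMH score is the sum of periventricular and
  deep Fazekas grades (0–6). PVS counts band as none (0), mild (1–10),
  moderate (11–20), frequent (21–40), severe (> 40), with
  moderate-to-severe = count ≥ 11.

## Synthetic data

The phantom is an ellipsoidal brain (semi-axes 0.42 × grid) of
Gaussian-noised tissue intensity (mean 100, SD 5) on a dark background,
with a central dark ventricle ellipsoid occupying 5% of brain volume,
n = 6 white-matter lesions, and, by default, one hyperintense stroke blob
plus a half-contrast edema halo that are recorded in the exclusion mask —
making the exclusion stage load-bearing in every default run. Lesions are
flat-core spheres (radius uniform in 1.2–2.5 mm) with Gaussian intensity
falloff (edge 0.6 mm) at contrast 60 intensity units = 12 tissue SDs;
truth masks are defined at the full-width-half-maximum of the profile.
Placement is rejection sampling inside a white-matter band, away from the
brain edge, the ventricles, the stroke blob and each other, which makes
truth ⊆ ICV and truth ∩ exclusions = ∅ hold by construction. The
defaults give a median planted load of ≈ 0.5 %ICV across seeds, matching
the burden scale of the cohort the generator emulates (median 0.5 %ICV),
and the full pipeline recovers truth at Dice ≈ 0.88–0.97 over seeds.

The cohort generator draws each binary risk factor independently within
phenotype from the published marginal rates, ages from per-group
Gaussians (61.7 ± 12.1 vs 57.7 ± 13.2 years), WMH %ICV from lognormals
matched to the published median and IQR ratio (the published IQRs are
slightly asymmetric beyond what a lognormal can express; the median and
quartile ratio are matched exactly), ordinal SVD scores from fixed level
distributions consistent with the published medians and dichotomized
rates, and leaves the CMB count missing for subjects without a simulated
susceptibility scan (≈ 29%/37% scanned). Only marginals are emulated: the
source tables report no joint distribution, so independence within
phenotype is a stated simplification, not an inference — an optional
post-hook accepts caller-supplied correlation structure. Consequently,
passing tests demonstrate that the statistical machinery is correct and
calibrated under known truth; they do not demonstrate that any particular
multivariable OR from real registry data would be reproduced, since those
depend on the unobserved joint structure.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; no global random state is touched, and
phantom/cohort/pipeline outputs are bit-identical across reruns of the
same config.

## Problem sizes

Defaults were chosen so a complete test-and-verification cycle runs on a
laptop-scale budget: phantoms at 64³ voxels (1 mm isotropic), voxel-test
calibrations on 20³ grids with 50–100 masks per group, logistic recovery
on cohorts of n = 1239 with 20 replicates in the test suite and 100 in
the acceptance script. All of these scale up by changing the specs.

## Known limitations

* No registration, bias-field handling, or multi-sequence fusion beyond
  a weighted average; inputs must be pre-aligned on one lattice.
* The brain-mask operation is a phantom-grade stand-in, not a
  skull-stripper.
* Voxel-wise inference ignores spatial autocorrelation (no cluster-extent
  or TFCE inference); BH is applied over voxels as exchangeable tests.
* The phantom has no MRI physics (no bias field, partial voluming beyond
  profile falloff, or k-space artifacts), so segmentation accuracy on it
  is an upper bound on real-data performance.
* Greedy matching is order-dependent by design (seeded); optimal
  matching is not implemented.
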