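# wmhkit

Tools for studying white matter hyperintensities (WMH) and other MRI
markers of cerebral small vessel disease in case-control stroke cohorts —
specifically the contrast between lacunar ischemic stroke (LIS) and deep
intracerebral hemorrhage (dICH), the two clinical faces of deep perforator
arteriopathy. The package is aimed at neuroimaging researchers who need a
tested, scriptable version of three analysis layers that usually live in
ad-hoc scripts:

1. **Threshold-based WMH segmentation with %ICV volumetrics.**
   Hyperintense voxels on a brain-extracted FLAIR image are selected by
   the rule *I(v) > μ + k·σ* with *k* = 1.3, where μ and σ are the mean
   and SD of in-brain intensities. Optional removal by a lesion
   distribution template is followed by a refinement pass on the
   Gaussian-smoothed, min–max-normalized image (voxels below intensity
   0.1 or z-score 0.95 are dropped), subtraction of exclusion masks
   (acute infarcts, old stroke lesions, perihematomal edema), and
   volumetrics: WMH volume normalized to intracranial volume,
   `%ICV = 100 · V_WMH / V_ICV`.

2. **Lesion probability mapping and voxel-wise comparison.** Probability
   maps are voxel-wise means of binary WMH masks on a common lattice.
   Groups (optionally 1:1 covariate-matched on age, sex, and vascular
   risk factors) are compared per voxel with a two-sided Wilcoxon
   rank-sum test (tie-corrected normal approximation; Kruskal–Wallis for
   more than two groups), corrected with Benjamini–Hochberg FDR, and
   summarized as thresholded difference maps and the percentage of WMH
   voxels that differ.

3. **Cohort association statistics.** Univariable tests (Pearson
   chi-square without continuity correction, two-sided Fisher exact,
   Mann–Whitney U, Welch t), two multivariable logistic regression models
   with Wald odds ratios and 95% CIs (`OR = e^β`, CI `e^{β ± 1.96·SE}`),
   variance-inflation-factor screening at VIF > 5, Cohen's kappa, and the
   standard SVD marker derivations (total WMH score = periventricular +
   deep Fazekas grade; perivascular-space severity bands none / mild 1–10
   / moderate 11–20 / frequent 21–40 / severe > 40).

Because clinical MRI and registry data cannot be redistributed, the
package ships a first-class synthetic-data module: brain phantoms with
known lesion truth masks (plus stroke/edema blobs that must be excluded,
not segmented) and cohort tables whose marginals are pinned to the
published LIS/dICH rates (834 vs 405 subjects, hypertension 72.3%/74.8%,
diabetes 35.7%/14.8%, and so on). Everything downstream is tested against
those known truths.

## Worked example

```python
from wmhkit import PhantomSpec, generate_brain_phantom, dice_coefficient
from wmhkit.segmentation import compute_brain_mask, segment_wmh
from wmhkit.stats import pearson_chi_square

flair, truth, icv, excl = generate_brain_phantom(PhantomSpec(seed=7))
brain = compute_brain_mask(flair)
res = segment_wmh(flair, brain, exclusions=[excl])
print(f"WMH load: {res.wmh_pct_icv:.3f} %ICV "
      f"({res.wmh_mask.n_voxels} voxels, ICV {res.icv_ml:.1f} ml)")
print(f"Dice vs truth: {dice_coefficient(res.wmh_mask, truth):.3f}")

r = pearson_chi_square([[603, 231], [303, 102]])
print(f"chi2 = {r.statistic:.3f}, df = {r.df}, p = {r.p_value:.3f}")
```

prints

```
WMH load: 0.602 %ICV (488 voxels, ICV 81.1 ml)
Dice vs truth: 0.914
chi2 = 0.876, df = 1, p = 0.349
```

The phantom carries about 0.5 %ICV of planted lesion load; the pipeline
recovers it with Dice ≈ 0.91 while the hyperintense stroke blob is kept
out of the final mask by the exclusion step. The chi-square line is the
hypertension row of the published baseline table (603/834 LIS vs 303/405
dICH patients hypertensive): the uncorrected Pearson test reproduces the
printed p = 0.349.

A command-line interface mirrors the library
(`wmhkit simulate-phantom | simulate-cohort | segment | probmap |
voxeltest | match | cohort-stats | run`); `wmhkit run --config run.yaml`
executes the whole simulate → segment → map → test → model chain and
writes a manifest with per-artifact checksums.

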