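"""Threshold-based WMH segmentation and %ICV volumetrics.

The pipeline mirrors a classical intensity-based FLAIR segmentation:

1. hyperintensity thresholding at mean + k·SD of in-brain intensities
   (k = 1.3 by default);
2. optional removal of voxels outside a lesion-distribution template;
3. refinement on a min–max-normalized, Gaussian-smoothed copy of the image,
   dropping voxels below an absolute intensity floor (0.1) or a z-score
   floor (0.95);
4. subtraction of user-supplied exclusion masks (acute infarcts, old stroke
   lesions, perihematomal edema);
5. volumetrics: WMH volume normalized to intracranial volume (%ICV).

Every step after the initial threshold only removes voxels, so the pipeline
is monotone; brain extraction itself is replaced by a simple automatic
threshold + morphology stand-in, because inputs are assumed co-registered
and skull-stripping is not the point of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .core import (
    BinaryMask,
    DegenerateInputError,
    InvalidSpecError,
    Volume,
    check_same_lattice,
)

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "compute_brain_mask",
    "threshold_hyperintensities",
    "apply_lesion_distribution_template",
    "refine_mask",
    "exclude_regions",
    "wmh_volume_pct_icv",
    "segment_wmh",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the WMH pipeline.

    k_sd: SD multiplier of the hyperintensity threshold.
    smooth_sigma_mm: Gaussian kernel width of the refinement smoothing, in
        mm (converted to voxel units per axis); sub-voxel by default so
        small lesions survive.
    intensity_floor: refinement floor on the smoothed min–max-normalized
        intensity (the floor is only meaningful on a [0, 1] scale).
    z_floor: refinement floor on the z-score of the smoothed image over the
        brain mask.
    template_min: voxels whose template value is <= this are removed; the
        default 0 only removes voxels the template rules out entirely.
    """

    k_sd: float = 1.3
    smooth_sigma_mm: float = 0.5
    intensity_floor: float = 0.1
    z_floor: float = 0.95
    template_min: float = 0.0

    def validate(self) -> None:
        if self.k_sd <= 0:
            raise InvalidSpecError("k_sd must be positive")
        if self.smooth_sigma_mm < 0:
            raise InvalidSpecError("smooth_sigma_mm must be non-negative")
        if not 0 <= self.intensity_floor <= 1:
            raise InvalidSpecError("intensity_floor must lie in [0, 1]")
        if not 0 <= self.template_min <= 1:
            raise InvalidSpecError("template_min must lie in [0, 1]")


@dataclass
class SegmentationResult:
    wmh_mask: BinaryMask
    wmh_volume_ml: float
    icv_ml: float
    wmh_pct_icv: float

    def to_dict(self, params: SegmentationParams | None = None) -> dict:
        out = {
            "wmh_voxels": self.wmh_mask.n_voxels,
            "wmh_volume_ml": self.wmh_volume_ml,
            "icv_ml": self.icv_ml,
            "wmh_pct_icv": self.wmh_pct_icv,
        }
        if params is not None:
            out["params"] = asdict(params)
        return out


def compute_brain_mask(
    volumes: Volume | Sequence[Volume], fusion_weight: float = 0.5
) -> BinaryMask:
    """Stand-in brain extraction: automatic threshold + morphology.

    With two volumes, segments their weighted-average fusion
    (w·first + (1−w)·second). The foreground is Otsu-thresholded, reduced
    to its largest connected component, and hole-filled, yielding a single
    connected head mask.
    """
    if isinstance(volumes, Volume):
        vols = [volumes]
    else:
        vols = list(volumes)
    if not 1 <= len(vols) <= 2:
        raise InvalidSpecError("compute_brain_mask takes one or two volumes")
    if not 0 <= fusion_weight <= 1:
        raise InvalidSpecError("fusion_weight must lie in [0, 1]")
    check_same_lattice(*vols)
    if len(vols) == 2:
        fused = fusion_weight * vols[0].values + (1 - fusion_weight) * vols[1].values
    else:
        fused = vols[0].values
    if np.ptp(fused) == 0:
        raise DegenerateInputError("constant image; cannot segment a brain")
    fg = fused > threshold_otsu(fused)
    if not fg.any():
        raise DegenerateInputError("automatic threshold found no foreground")
    labels = label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == int(np.argmax(counts))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg, vols[0].voxel_size_mm, vols[0].affine)


def threshold_hyperintensities(
    flair: Volume, brain_mask: BinaryMask, k_sd: float = 1.3
) -> BinaryMask:
    """Voxels strictly above mean + k_sd·SD of in-brain intensities.

    Ties at exactly the cut-off are excluded ("above the mean" means strict
    exceedance); a constant in-brain image therefore yields an empty mask.
    """
    check_same_lattice(flair, brain_mask)
    if brain_mask.n_voxels == 0:
        raise DegenerateInputError("empty brain mask")
    inside = flair.values[brain_mask.values]
    cutoff = inside.mean() + k_sd * inside.std()
    return brain_mask.with_values(brain_mask.values & (flair.values > cutoff))


def apply_lesion_distribution_template(
    mask: BinaryMask, template: Volume, template_min: float = 0.0
) -> BinaryMask:
    """Remove mask voxels where the lesion-distribution template is
    <= template_min. Never adds voxels."""
    check_same_lattice(mask, template)
    if template.values.min() < 0 or template.values.max() > 1:
        raise InvalidSpecError("template values must lie in [0, 1]")
    return mask.with_values(mask.values & (template.values > template_min))


def _smoothed_normalized(
    flair: Volume, brain_mask: BinaryMask, smooth_sigma_mm: float
) -> np.ndarray:
    inside = flair.values[brain_mask.values]
    lo, hi = inside.min(), inside.max()
    if hi == lo:
        raise DegenerateInputError("constant in-brain intensities")
    norm = np.clip((flair.values - lo) / (hi - lo), 0.0, 1.0)
    if smooth_sigma_mm > 0:
        sigma_vox = [smooth_sigma_mm / v for v in flair.voxel_size_mm]
        norm = ndimage.gaussian_filter(norm, sigma=sigma_vox)
    return norm


def refine_mask(
    mask: BinaryMask,
    flair: Volume,
    brain_mask: BinaryMask,
    params: SegmentationParams = SegmentationParams(),
) -> BinaryMask:
    """Refinement floors on the smoothed normalized image.

    In-brain intensities are min–max normalized to [0, 1], Gaussian-smoothed
    with smooth_sigma_mm, and mask voxels are dropped when the smoothed
    value falls below intensity_floor or its z-score (over brain voxels of
    the smoothed image) falls below z_floor.
    """
    check_same_lattice(mask, flair, brain_mask)
    params.validate()
    smoothed = _smoothed_normalized(flair, brain_mask, params.smooth_sigma_mm)
    inside = smoothed[brain_mask.values]
    mu, sd = inside.mean(), inside.std()
    if sd == 0:
        raise DegenerateInputError("zero variance after smoothing")
    z = (smoothed - mu) / sd
    keep = (smoothed >= params.intensity_floor) & (z >= params.z_floor)
    return mask.with_values(mask.values & keep)


def exclude_regions(
    mask: BinaryMask, exclusions: BinaryMask | Sequence[BinaryMask]
) -> BinaryMask:
    """Set difference mask \\ union of exclusion masks (manual removal of
    acute/old stroke lesions and perihematomal edema)."""
    if isinstance(exclusions, BinaryMask):
        exclusions = [exclusions]
    out = mask.values.copy()
    for ex in exclusions:
        check_same_lattice(mask, ex)
        out &= ~ex.values
    return mask.with_values(out)


def wmh_volume_pct_icv(
    wmh: BinaryMask, icv: BinaryMask
) -> SegmentationResult:
    """Volumes from voxel counts; WMH reported as a percentage of ICV."""
    check_same_lattice(wmh, icv)
    if icv.n_voxels == 0:
        raise DegenerateInputError("empty ICV mask")
    outside = int((wmh.values & ~icv.values).sum())
    if outside:
        import warnings

        warnings.warn(
            f"{outside} WMH voxels lie outside the ICV mask", stacklevel=2
        )
    wmh_ml = wmh.volume_ml()
    icv_ml = icv.volume_ml()
    return SegmentationResult(wmh, wmh_ml, icv_ml, 100.0 * wmh_ml / icv_ml)


def segment_wmh(
    flair: Volume,
    brain_mask: BinaryMask,
    template: Volume | None = None,
    exclusions: Sequence[BinaryMask] = (),
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Full pipeline: threshold → template removal → refinement →
    exclusion → volumetrics. Each stage only removes voxels."""
    params.validate()
    mask = threshold_hyperintensities(flair, brain_mask, params.k_sd)
    if template is not None:
        mask = apply_lesion_distribution_template(mask, template, params.template_min)
    mask = refine_mask(mask, flair, brain_mask, params)
    mask = exclude_regions(mask, list(exclusions))
    return wmh_volume_pct_icv(mask, brain_mask)
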