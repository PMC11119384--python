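"""Synthetic inputs: brain phantoms with known lesion truth, and case-control
cohort tables with the marginal structure of a lacunar-stroke (LIS) versus
deep intracerebral hemorrhage (dICH) registry.

The phantom is an ellipsoidal "brain" of Gaussian-noised tissue intensity on
a dark background, with a dark central ventricle region, hyperintense
white-matter lesions of known truth masks, and (optionally) one larger
hyperintense stroke/edema blob that belongs in the exclusion mask rather
than in the lesion truth — so the subtractive exclusion step of the
segmentation pipeline is genuinely exercised.

The cohort generator draws each binary risk factor independently within
phenotype from its marginal prevalence, ages from per-group Gaussians, and
the WMH burden (%ICV) from per-group lognormals. Only marginals are
emulated; no joint correlation structure is imposed (an optional hook
accepts a caller-supplied post-processing function).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .core import BinaryMask, InvalidSpecError, ProbabilityMap, Volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_brain_phantom",
    "generate_cohort",
    "generate_mask_population",
    "COHORT_COLUMNS",
    "DEFAULT_PREVALENCES",
]


# ----------------------------------------------------------------------------
# Brain phantom
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic FLAIR-like brain volume.

    Intensities are in arbitrary units. The default contrast
    (lesion 160 vs tissue 100 with SD 5) puts lesion cores 12 tissue-SDs
    above the mean, far beyond the 1.3-SD segmentation cut, so truth
    recovery failures indicate pipeline defects rather than overlap of the
    intensity distributions.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_intensity_mean: float = 100.0
    brain_intensity_sd: float = 5.0
    lesion_intensity_mean: float = 160.0
    n_lesions: int = 6
    lesion_radius_range_mm: tuple[float, float] = (1.2, 2.5)
    ventricle_fraction: float = 0.05
    include_stroke_lesion: bool = True
    include_edema: bool = True
    seed: int = 0

    def validate(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel sizes must be positive")
        if self.brain_intensity_sd <= 0:
            raise InvalidSpecError("brain_intensity_sd must be positive")
        if self.n_lesions < 0:
            raise InvalidSpecError("n_lesions must be non-negative")
        lo, hi = self.lesion_radius_range_mm
        if lo <= 0 or hi < lo:
            raise InvalidSpecError("lesion_radius_range_mm must be positive and ordered")
        if not (0 <= self.ventricle_fraction < 1):
            raise InvalidSpecError("ventricle_fraction must lie in [0, 1)")
        contrast = self.lesion_intensity_mean - self.brain_intensity_mean
        if contrast < 3 * self.brain_intensity_sd:
            raise InvalidSpecError(
                "lesion contrast below 3 tissue SDs; lesions would not be "
                "separable by SD-based thresholding"
            )


def _ellipsoid(shape: tuple[int, ...], center: np.ndarray,
               semi_axes: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def _distance_mm(shape, center, voxel_size) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, voxel_size))
    return np.sqrt(d2)


# Gaussian edge width of lesion intensity falloff beyond the nominal radius.
_EDGE_MM = 0.6
# Truth masks are defined at full-width-half-maximum of the intensity
# profile: flat core of radius r plus falloff down to half contrast.
_FWHM_EXTRA = _EDGE_MM * np.sqrt(2.0 * np.log(2.0))


def generate_brain_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, BinaryMask, BinaryMask, BinaryMask]:
    """Build one phantom: FLAIR-like volume, WMH truth, ICV truth, exclusions.

    Deterministic: identical specs (including seed) give bit-identical
    outputs. Lesion centers are rejection-sampled inside the white matter
    (away from the brain edge, the ventricles, each other, and the stroke
    blob), so the conservation invariants truth ⊆ ICV and
    truth ∩ exclusions = ∅ hold by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0

    brain_axes = 0.42 * np.asarray(shape, dtype=float)
    icv = _ellipsoid(shape, center, brain_axes)
    vent_axes = brain_axes * spec.ventricle_fraction ** (1.0 / 3.0)
    ventricle = _ellipsoid(shape, center, vent_axes) & icv

    contrast = spec.lesion_intensity_mean - spec.brain_intensity_mean
    image = np.zeros(shape, dtype=np.float64)
    image[icv] = spec.brain_intensity_mean
    image[ventricle] = 0.2 * spec.brain_intensity_mean

    # Candidate white-matter band: comfortably inside the brain and away
    # from the ventricles, so lesion + falloff stays inside ICV.
    wm_band = (
        _ellipsoid(shape, center, brain_axes * 0.78)
        & ~_ellipsoid(shape, center, np.maximum(vent_axes * 1.6, vent_axes + 3.0))
    )
    wm_idx = np.argwhere(wm_band)
    if spec.n_lesions > 0 and len(wm_idx) == 0:
        raise InvalidSpecError("grid too small to place lesions inside the brain")

    def add_blob(ctr: np.ndarray, radius_mm: float, amplitude: float) -> np.ndarray:
        """Add a flat-core Gaussian-falloff blob; return its FWHM truth mask."""
        d = _distance_mm(shape, ctr, vox)
        profile = amplitude * np.exp(
            -np.maximum(d - radius_mm, 0.0) ** 2 / (2.0 * _EDGE_MM ** 2)
        )
        profile[d > radius_mm + 4.0 * _EDGE_MM] = 0.0
        image[:] += np.where(icv & ~ventricle, profile, 0.0)
        return (d <= radius_mm + _FWHM_EXTRA) & icv & ~ventricle

    exclusions = np.zeros(shape, dtype=bool)
    placed: list[tuple[np.ndarray, float]] = []

    if spec.include_stroke_lesion:
        ctr = wm_idx[rng.integers(len(wm_idx))].astype(float)
        stroke_r = 2.0 * spec.lesion_radius_range_mm[1]
        exclusions |= add_blob(ctr, stroke_r, contrast)
        if spec.include_edema:
            # perihematomal/peri-infarct edema: wider, half-contrast halo
            d = _distance_mm(shape, ctr, vox)
            halo = (d <= stroke_r + 3.0) & icv & ~ventricle
            image[halo & ~exclusions] += 0.5 * contrast
            exclusions |= halo
        placed.append((ctr, stroke_r + 3.0))

    truth_wmh = np.zeros(shape, dtype=bool)
    min_r, max_r = spec.lesion_radius_range_mm
    n_placed = 0
    attempts = 0
    while n_placed < spec.n_lesions and attempts < 200 * max(spec.n_lesions, 1):
        attempts += 1
        ctr = wm_idx[rng.integers(len(wm_idx))].astype(float)
        r = float(rng.uniform(min_r, max_r))
        min_vox = float(np.min(vox))
        ok = all(
            np.linalg.norm((ctr - c) * vox) > (r + pr) + 2.0 * min_vox
            for c, pr in placed
        )
        if not ok:
            continue
        truth_wmh |= add_blob(ctr, r, contrast)
        placed.append((ctr, r))
        n_placed += 1
    if n_placed < spec.n_lesions:
        raise InvalidSpecError(
            f"could only place {n_placed}/{spec.n_lesions} lesions; "
            "grid too crowded"
        )

    noise = rng.normal(0.0, spec.brain_intensity_sd, size=shape)
    image += noise
    np.clip(image, 0.0, None, out=image)

    flair = Volume(image, tuple(vox), None)
    return (
        flair,
        BinaryMask(truth_wmh, tuple(vox), flair.affine),
        BinaryMask(icv, tuple(vox), flair.affine),
        BinaryMask(exclusions, tuple(vox), flair.affine),
    )


# ----------------------------------------------------------------------------
# Cohort tables
# ----------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id", "phenotype", "age", "sex",
    "hypertension", "diabetes", "hyperlipidemia", "cad", "ckd",
    "prior_is", "prior_ich", "smoking", "alcohol",
    "antiplatelet", "lipid_lowering",
    "fazekas_pv", "fazekas_deep", "bgpvs_cat", "csopvs_cat",
    "lacune_n", "cmb_n", "wmh_pct_icv",
]

# Marginal prevalence of each binary factor, (LIS, dICH).
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "sex": (0.723, 0.721),  # male
    "hypertension": (0.723, 0.748),
    "diabetes": (0.357, 0.148),
    "hyperlipidemia": (0.353, 0.143),
    "cad": (0.053, 0.040),
    "ckd": (0.110, 0.111),
    "prior_is": (0.101, 0.042),
    "prior_ich": (0.028, 0.059),
    "smoking": (0.415, 0.306),
    "alcohol": (0.284, 0.383),
    "antiplatelet": (0.121, 0.072),
    "lipid_lowering": (0.096, 0.059),
}

# Ordinal score distributions (probabilities over levels 0..k), (LIS, dICH).
# Chosen so medians and the dichotomized proportions (score >= 2,
# moderate-to-severe PVS, any lacune, any CMB) sit at the cohort's marginal
# rates.
_FAZEKAS_PV = (
    (0.150, 0.426, 0.300, 0.124),
    (0.140, 0.398, 0.320, 0.142),
)
_FAZEKAS_DEEP = (
    (0.300, 0.369, 0.230, 0.101),
    (0.280, 0.337, 0.270, 0.113),
)
_BGPVS = (
    (0.040, 0.359, 0.400, 0.150, 0.051),
    (0.040, 0.377, 0.390, 0.140, 0.053),
)
_CSOPVS = (
    (0.020, 0.120, 0.500, 0.260, 0.100),
    (0.020, 0.116, 0.500, 0.260, 0.104),
)


def _lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matching the median and the IQR ratio."""
    from scipy.stats import norm

    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * norm.ppf(0.75))
    return float(mu), float(sigma)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic LIS/dICH cohort table.

    Defaults pin every marginal to the registry's printed rates:
    834 LIS / 405 dICH; risk-factor prevalences per group; ages
    N(61.7, 12.1) and N(57.7, 13.2) years; WMH %ICV lognormal with median
    0.5 and quartiles (0.3, 1.2) for LIS and (0.2, 1.2) for dICH.
    """

    n_lis: int = 834
    n_dich: int = 405
    prevalences: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    age_mean: tuple[float, float] = (61.7, 57.7)
    age_sd: tuple[float, float] = (12.1, 13.2)
    wmh_quartiles: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.5, 0.3, 1.2),
        (0.5, 0.2, 1.2),
    )
    lacune_prevalence: tuple[float, float] = (0.415, 0.353)
    lacune_extra_mean: tuple[float, float] = (1.0, 0.5)  # count = 1 + Poisson
    cmb_available: tuple[float, float] = (0.291, 0.365)
    cmb_prevalence: tuple[float, float] = (0.383, 0.628)
    cmb_extra_mean: tuple[float, float] = (3.0, 2.5)
    seed: int = 0
    # optional hook to impose correlation structure on the sampled table
    post_hook: Callable[[pd.DataFrame, np.random.Generator], pd.DataFrame] | None = None

    def validate(self) -> None:
        if self.n_lis < 0 or self.n_dich < 0:
            raise InvalidSpecError("group sizes must be non-negative")
        for name, (p0, p1) in self.prevalences.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise InvalidSpecError(f"prevalence of {name!r} outside [0, 1]")
        for p in (*self.lacune_prevalence, *self.cmb_available, *self.cmb_prevalence):
            if not 0 <= p <= 1:
                raise InvalidSpecError("prevalence outside [0, 1]")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort table with n_lis + n_dich subject rows.

    Binary factors are independent Bernoulli draws within phenotype; ordinal
    SVD scores come from fixed per-group level distributions; the CMB count
    is missing (NaN) for subjects without a simulated susceptibility scan.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g, (label, n) in enumerate((("LIS", spec.n_lis), ("dICH", spec.n_dich))):
        if n == 0:
            continue
        df = pd.DataFrame({"phenotype": [label] * n})
        df["age"] = rng.normal(spec.age_mean[g], spec.age_sd[g], n).round(1)
        for name, pv in spec.prevalences.items():
            df[name] = (rng.random(n) < pv[g]).astype(int)
        df["fazekas_pv"] = rng.choice(4, size=n, p=_FAZEKAS_PV[g])
        df["fazekas_deep"] = rng.choice(4, size=n, p=_FAZEKAS_DEEP[g])
        df["bgpvs_cat"] = rng.choice(5, size=n, p=_BGPVS[g])
        df["csopvs_cat"] = rng.choice(5, size=n, p=_CSOPVS[g])
        has_lacune = rng.random(n) < spec.lacune_prevalence[g]
        df["lacune_n"] = np.where(
            has_lacune, 1 + rng.poisson(spec.lacune_extra_mean[g], n), 0
        )
        scanned = rng.random(n) < spec.cmb_available[g]
        has_cmb = rng.random(n) < spec.cmb_prevalence[g]
        cmb = np.where(has_cmb, 1 + rng.poisson(spec.cmb_extra_mean[g], n), 0)
        df["cmb_n"] = np.where(scanned, cmb, np.nan)
        med, q1, q3 = spec.wmh_quartiles[g]
        mu, sigma = _lognormal_from_quartiles(med, q1, q3)
        df["wmh_pct_icv"] = np.exp(rng.normal(mu, sigma, n))
        frames.append(df)

    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(out))])
    out = out[COHORT_COLUMNS]
    if spec.post_hook is not None:
        out = spec.post_hook(out, rng)
    return out


# ----------------------------------------------------------------------------
# Mask populations
# ----------------------------------------------------------------------------

def generate_mask_population(
    prob_map: ProbabilityMap, n: int, seed: int
) -> list[BinaryMask]:
    """Draw n binary masks, voxel-wise Bernoulli(prob_map)."""
    if n < 1:
        raise InvalidSpecError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        BinaryMask(
            rng.random(prob_map.shape) < prob_map.values,
            prob_map.voxel_size_mm,
            prob_map.affine,
        )
        for _ in range(n)
    ]
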