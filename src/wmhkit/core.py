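"""Core spatial containers shared across the toolkit.

All images in a pipeline run live on one common voxel lattice: same grid
shape and same world affine. Registration is assumed to have happened
upstream; nothing here resamples or reorients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "ProbabilityMap",
    "WmhKitError",
    "InvalidSpecError",
    "DegenerateInputError",
    "LatticeMismatchError",
    "check_same_lattice",
    "dice_coefficient",
]


class WmhKitError(ValueError):
    """Base class for toolkit errors."""


class InvalidSpecError(WmhKitError):
    """A simulation spec or parameter set violates its invariants."""


class DegenerateInputError(WmhKitError):
    """Input is structurally valid but carries no usable signal
    (constant image, empty mask, zero variance...)."""


class LatticeMismatchError(WmhKitError):
    """Two images that must share a voxel lattice do not."""


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class Volume:
    """A 3D scalar image with voxel sizes (mm) and a world affine."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidSpecError("Volume requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidSpecError("Volume values must be finite")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), zooms, img.affine)


@dataclass
class BinaryMask:
    """A 3D boolean image on the same lattice as its companion Volume."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise InvalidSpecError("BinaryMask requires a 3D array")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise InvalidSpecError("mask values must be 0/1")
        self.values = arr.astype(bool)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def volume_ml(self) -> float:
        """Mask volume in millilitres (1 ml = 1000 mm³)."""
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.voxel_size_mm, self.affine)

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.uint8), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0, zooms, img.affine)


@dataclass
class ProbabilityMap:
    """Per-voxel lesion frequency in [0, 1] with contributing sample size n."""

    values: np.ndarray
    n: int
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidSpecError("ProbabilityMap requires a 3D array")
        if self.values.min() < 0 or self.values.max() > 1:
            raise InvalidSpecError("probabilities must lie in [0, 1]")
        self.n = int(self.n)
        if self.affine is None:
            self.affine = _default_affine(tuple(self.voxel_size_mm))
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))


def check_same_lattice(*images) -> None:
    """Raise LatticeMismatchError unless all images share shape and affine."""
    ref = images[0]
    for im in images[1:]:
        if im.shape != ref.shape:
            raise LatticeMismatchError(
                f"grid shapes differ: {im.shape} vs {ref.shape}"
            )
        if not np.allclose(im.affine, ref.affine, atol=1e-6):
            raise LatticeMismatchError("affines differ")


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); defined as 1.0 for two empty masks."""
    check_same_lattice(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)
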