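"""Volume I/O, intensity normalisation, smoothing and cohort flattening.

Voxel flattening convention
---------------------------
Whenever a 3-D volume is flattened to a voxel vector, C (row-major) order is
used: the *last* axis varies fastest.  All masked operations index voxels as
``volume.ravel(order="C")[flat_mask_indices]``; :func:`stack_cohort` and
:func:`unstack_subject` are exact inverses under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "SubjectMatrix",
    "read_volume",
    "write_volume",
    "compute_suvr",
    "smooth_gaussian",
    "fwhm_to_sigma",
    "common_mask",
    "stack_cohort",
    "unstack_subject",
]

#: conversion factor between Gaussian FWHM and standard deviation
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ImageVolume:
    """A 3-D intensity volume with a voxel-to-world affine."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.voxels.ndim}-D "
                f"with shape {self.voxels.shape}"
            )
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"degenerate volume shape {self.voxels.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge length per axis in world units (mm)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class SubjectMatrix:
    """A subjects-by-voxels data matrix restricted to an analysis mask.

    Row *i* holds the in-mask voxels of subject *i*, flattened in C order
    (see module docstring).  ``modality`` tags the imaging contrast
    (``"structural"`` or ``"metabolic"``).
    """

    data: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray
    modality: str = "structural"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.group_labels = np.asarray(self.group_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length does not match data rows")
        if len(self.group_labels) != self.data.shape[0]:
            raise ValueError("group_labels length does not match data rows")
        if len(np.unique(self.group_labels)) < 1:
            raise ValueError("at least one group label required")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def flat_indices(self) -> np.ndarray:
        """Indices of in-mask voxels in the C-order flattened volume."""
        return np.flatnonzero(self.mask.ravel(order="C"))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI volume.

    Raises ``FileNotFoundError`` for missing paths and ``ValueError`` (naming
    the path) for non-3-D images or unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise ValueError(f"could not read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D {data.shape}"
        )
    return ImageVolume(voxels=np.asarray(data, dtype=np.float64), affine=img.affine)


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write ``volume`` as NIfTI-1; round-trips values and affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), volume.affine)
    nib.save(img, str(path))
    return path


def compute_suvr(volume: ImageVolume, brain_mask: np.ndarray) -> ImageVolume:
    """Scale intensities to the mean in-mask uptake (SUVr normalisation).

    The output's in-mask mean is exactly 1.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("brain mask is empty")
    mean = float(volume.voxels[mask].mean())
    if mean <= 0:
        raise ValueError(f"non-positive in-mask mean ({mean:g}); cannot normalise")
    return ImageVolume(voxels=volume.voxels / mean, affine=volume.affine.copy())


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian standard deviation corresponding to a given FWHM."""
    return fwhm / _FWHM_FACTOR


def smooth_gaussian(volume: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Separable 3-D Gaussian smoothing with FWHM given in millimetres.

    ``fwhm_mm = 0`` is the identity.  The kernel width is converted to voxel
    units per axis using the affine's voxel size.
    """
    if fwhm_mm < 0:
        raise ValueError(f"negative FWHM: {fwhm_mm}")
    if fwhm_mm == 0:
        return ImageVolume(voxels=volume.voxels.copy(), affine=volume.affine.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / volume.voxel_size
    smoothed = ndimage.gaussian_filter(volume.voxels, sigma=sigma_vox)
    return ImageVolume(voxels=smoothed, affine=volume.affine.copy())


def common_mask(volumes: Sequence[ImageVolume]) -> np.ndarray:
    """Default analysis mask: voxels nonzero in every subject."""
    if not volumes:
        raise ValueError("no volumes given")
    mask = np.ones(volumes[0].shape, dtype=bool)
    for vol in volumes:
        mask &= vol.voxels != 0
    return mask


def stack_cohort(
    volumes: Sequence[ImageVolume],
    mask: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    group_labels: Sequence | None = None,
    modality: str = "structural",
) -> SubjectMatrix:
    """Flatten a cohort of volumes into a subjects-by-voxels matrix."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(len(volumes))]
    if group_labels is None:
        group_labels = ["all"] * len(volumes)
    flat_idx = np.flatnonzero(mask.ravel(order="C"))
    rows = np.empty((len(volumes), flat_idx.size))
    for i, vol in enumerate(volumes):
        if vol.shape != mask.shape:
            raise ValueError(
                f"subject {subject_ids[i]}: volume shape {vol.shape} does not "
                f"match mask shape {mask.shape}"
            )
        rows[i] = vol.voxels.ravel(order="C")[flat_idx]
    return SubjectMatrix(
        data=rows,
        mask=mask,
        subject_ids=list(subject_ids),
        group_labels=np.asarray(group_labels),
        modality=modality,
    )


def unstack_subject(matrix: SubjectMatrix, row: int, fill: float = 0.0) -> np.ndarray:
    """Re-embed one subject row into a full 3-D volume (out-of-mask = fill)."""
    flat = np.full(matrix.mask.size, fill, dtype=np.float64)
    flat[matrix.flat_indices] = matrix.data[row]
    return flat.reshape(matrix.mask.shape, order="C")
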