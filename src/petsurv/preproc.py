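"""Volume handling and feature-matrix assembly for registered brain PET scans.

All volumes are assumed to be already registered to a common grid.  The
preprocessing chain mirrors routine voxel-based metabolic analysis: Gaussian
smoothing, intensity normalization to the whole-brain mean, and reduction of
the 3-D grid to a subjects x masked-voxels feature matrix in which each voxel
is one feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BrainVolume",
    "BrainMask",
    "FeatureMatrix",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "normalize_whole_brain",
    "gaussian_smooth",
    "assemble_features",
]

#: full width at half maximum of a Gaussian, in units of its sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BrainVolume:
    """One subject's registered 3-D intensity grid with its voxel-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume {self.subject_id!r} must be 3-D, got {self.data.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(
                f"volume {self.subject_id!r} contains {n_bad} non-finite voxel(s)"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths, from the norms of the affine's spatial columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BrainMask:
    """Binary whole-brain mask on the cohort's common grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.n_voxels < 1:
            raise ValueError("mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class FeatureMatrix:
    """Subjects x masked-voxels matrix with a map back to the 3-D grid.

    Columns follow row-major (C) order over the grid, so the layout is a pure
    function of the mask and is stable across runs and platforms.
    """

    values: np.ndarray                 # (n_subjects, n_voxels)
    voxel_index: np.ndarray            # (n_voxels, 3) int voxel coordinates
    subject_ids: list[str]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_volume(self, row: np.ndarray) -> np.ndarray:
        """Scatter one feature row back into a dense 3-D grid (zeros outside)."""
        row = np.asarray(row, dtype=float)
        if row.shape != (self.n_voxels,):
            raise ValueError("row length does not match the number of masked voxels")
        vol = np.zeros(self.grid_shape, dtype=float)
        vol[tuple(self.voxel_index.T)] = row
        return vol

    def save(self, path: str | Path) -> None:
        """Write values as .npz with a sidecar JSON voxel-index map."""
        path = Path(path)
        np.savez_compressed(path, values=self.values)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "subject_ids": list(self.subject_ids),
                    "grid_shape": list(self.grid_shape),
                    "affine": self.affine.tolist(),
                    "voxel_index": self.voxel_index.tolist(),
                }
            )
        )


def load_volume(path: str | Path, expected_shape: Sequence[int] | None = None) -> BrainVolume:
    """Read a NIfTI-1 volume, failing loudly on anything that is not a clean 3-D grid."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D image, got {data.ndim}-D")
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path.name}: {n_bad} non-finite voxel(s)")
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path.name}: shape {data.shape} != expected {tuple(expected_shape)}"
        )
    return BrainVolume(data=data, affine=np.asarray(img.affine), subject_id=path.stem)


def save_volume(volume: BrainVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("mask image must be 3-D")
    return BrainMask(data=data > 0)


def save_mask(mask: BrainMask, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def normalize_whole_brain(volume: BrainVolume, mask: BrainMask) -> BrainVolume:
    """Divide masked voxels by the whole-brain mean; zero elsewhere.

    After normalization the masked mean is exactly 1, so values below/above 1
    read as relative hypo-/hyper-metabolism.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume {volume.subject_id!r} shape {volume.shape} != mask {mask.shape}"
        )
    masked = volume.data[mask.data]
    mean = float(masked.mean())
    if mean <= 0:
        raise ValueError(
            f"volume {volume.subject_id!r}: whole-brain mean {mean:g} is not positive"
        )
    out = np.zeros_like(volume.data)
    out[mask.data] = masked / mean
    return BrainVolume(data=out, affine=volume.affine, subject_id=volume.subject_id)


def gaussian_smooth(
    volume: BrainVolume,
    fwhm_mm: float,
    mode: str = "reflect",
    min_fwhm_voxels: float = 0.5,
    mask: BrainMask | None = None,
) -> BrainVolume:
    """Isotropic Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units from
    the affine.  Without a mask, the default symmetric boundary mode conserves
    total in-grid intensity for the normalized kernel.  With a mask, smoothing
    is confined to it: the masked data are convolved and renormalized by the
    smoothed mask support, so no intensity bleeds across the brain boundary
    (constants inside the mask stay constant) and voxels outside are zeroed.
    A kernel narrower than ``min_fwhm_voxels`` on every axis is a no-op.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel_mm = volume.voxel_sizes_mm()
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel sizes derived from the affine must be positive")
    fwhm_vox = fwhm_mm / voxel_mm
    if np.all(fwhm_vox < min_fwhm_voxels):
        return BrainVolume(
            data=volume.data.copy(), affine=volume.affine, subject_id=volume.subject_id
        )
    sigma_vox = fwhm_vox / FWHM_PER_SIGMA
    if mask is None:
        smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode=mode)
    else:
        if mask.shape != volume.shape:
            raise ValueError("mask shape does not match the volume")
        m = mask.data.astype(float)
        num = ndimage.gaussian_filter(volume.data * m, sigma=sigma_vox, mode="constant")
        den = ndimage.gaussian_filter(m, sigma=sigma_vox, mode="constant")
        smoothed = np.zeros_like(volume.data)
        inside = mask.data
        smoothed[inside] = num[inside] / den[inside]
    return BrainVolume(data=smoothed, affine=volume.affine, subject_id=volume.subject_id)


def assemble_features(volumes: Sequence[BrainVolume], mask: BrainMask) -> FeatureMatrix:
    """Stack masked voxel intensities into a subjects x voxels matrix.

    Every masked voxel becomes one feature (column), in deterministic row-major
    grid order; ``voxel_index`` maps each column back to its 3-D coordinate.
    """
    if not volumes:
        raise ValueError("no volumes given")
    for vol in volumes:
        if vol.shape != mask.shape:
            raise ValueError(
                f"subject {vol.subject_id!r}: shape {vol.shape} != mask {mask.shape}"
            )
    voxel_index = np.argwhere(mask.data)  # C order = row-major
    values = np.stack([vol.data[mask.data] for vol in volumes])
    return FeatureMatrix(
        values=values,
        voxel_index=voxel_index,
        subject_ids=[vol.subject_id for vol in volumes],
        grid_shape=tuple(mask.shape),
        affine=volumes[0].affine.copy(),
    )
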