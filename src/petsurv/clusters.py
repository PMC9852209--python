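"""Contiguous-cluster mapping of selected voxels: the explainability layer.

Each class's selected voxel set is decomposed into 3-D connected components;
components larger than an extent threshold (more than 100 contiguous voxels
by default) are reported with their peak/centroid coordinates (voxel indices
and affine-mapped mm) and their metabolic direction relative to the
whole-brain mean of the class's intensity-normalized scans (mean relative
intensity < 1: hypometabolic, >= 1: hypermetabolic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .preproc import BrainVolume

__all__ = [
    "VoxelCluster",
    "VoxelClusterReport",
    "extract_clusters",
    "localize_cluster",
    "cluster_direction",
    "build_cluster_report",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VoxelCluster:
    """One contiguous component of selected voxels."""

    voxels: np.ndarray                       # (extent, 3) int coordinates
    extent: int
    centroid_vox: np.ndarray | None = None
    centroid_mm: np.ndarray | None = None
    peak_vox: np.ndarray | None = None
    peak_mm: np.ndarray | None = None
    direction: str | None = None             # "hypo" | "hyper"
    mean_relative_intensity: float | None = None

    def as_row(self) -> dict:
        return {
            "extent": self.extent,
            "centroid_x_mm": None if self.centroid_mm is None else float(self.centroid_mm[0]),
            "centroid_y_mm": None if self.centroid_mm is None else float(self.centroid_mm[1]),
            "centroid_z_mm": None if self.centroid_mm is None else float(self.centroid_mm[2]),
            "peak_i": None if self.peak_vox is None else int(self.peak_vox[0]),
            "peak_j": None if self.peak_vox is None else int(self.peak_vox[1]),
            "peak_k": None if self.peak_vox is None else int(self.peak_vox[2]),
            "direction": self.direction,
            "mean_relative_intensity": self.mean_relative_intensity,
        }


def extract_clusters(
    selected_mask: np.ndarray, min_extent: int = 100, connectivity: int = 26
) -> list[VoxelCluster]:
    """Connected components of a binary voxel mask, filtered by extent.

    Only components with strictly more than ``min_extent`` voxels are kept
    (an extent of exactly ``min_extent`` is excluded), sorted by descending
    extent with ties broken by first voxel in grid order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(selected_mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("selected_mask must be 3-D")
    labelled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labelled == lab)
        if voxels.shape[0] > min_extent:
            clusters.append(VoxelCluster(voxels=voxels, extent=int(voxels.shape[0])))
    clusters.sort(key=lambda c: (-c.extent, tuple(c.voxels[0])))
    return clusters


def localize_cluster(
    cluster: VoxelCluster,
    affine: np.ndarray,
    mean_relative_volume: np.ndarray | None = None,
) -> VoxelCluster:
    """Fill in centroid (and, given a class mean volume, peak) coordinates.

    The centroid is the unweighted mean voxel coordinate mapped through the
    affine.  The peak is the cluster voxel with the largest deviation
    |mean relative intensity - 1| across the class's normalized scans.
    """
    if cluster.extent == 0:
        raise ValueError("empty cluster")
    affine = np.asarray(affine, dtype=float)
    centroid = cluster.voxels.mean(axis=0)
    cluster.centroid_vox = centroid
    cluster.centroid_mm = nib.affines.apply_affine(affine, centroid)
    if mean_relative_volume is not None:
        dev = np.abs(mean_relative_volume[tuple(cluster.voxels.T)] - 1.0)
        peak = cluster.voxels[int(np.argmax(dev))]
        cluster.peak_vox = peak
        cluster.peak_mm = nib.affines.apply_affine(affine, peak.astype(float))
    return cluster


def cluster_direction(
    cluster: VoxelCluster, class_volumes: Sequence[BrainVolume] | Sequence[np.ndarray]
) -> VoxelCluster:
    """Label a cluster hypo-/hypermetabolic from the class's normalized scans.

    The mean over cluster voxels and class subjects is compared with the
    whole-brain reference of 1 (volumes must be intensity-normalized);
    values < 1 are hypo, >= 1 hyper (boundary counts as hyper).
    """
    if len(class_volumes) == 0:
        raise ValueError("empty subject set")
    grids = [v.data if isinstance(v, BrainVolume) else np.asarray(v) for v in class_volumes]
    idx = tuple(cluster.voxels.T)
    mean_rel = float(np.mean([g[idx].mean() for g in grids]))
    cluster.mean_relative_intensity = mean_rel
    cluster.direction = "hypo" if mean_rel < 1.0 else "hyper"
    return cluster


@dataclass
class VoxelClusterReport:
    """All surviving clusters of one class's discriminant voxels."""

    class_id: int
    clusters: list[VoxelCluster] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": self.class_id, **c.as_row()} for c in self.clusters]
        return pd.DataFrame(
            rows,
            columns=[
                "class", "extent",
                "centroid_x_mm", "centroid_y_mm", "centroid_z_mm",
                "peak_i", "peak_j", "peak_k",
                "direction", "mean_relative_intensity",
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_frame().to_json(orient="records", indent=1))

    def cluster_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(grid_shape, dtype=bool)
        for c in self.clusters:
            mask[tuple(c.voxels.T)] = True
        return mask


def build_cluster_report(
    class_id: int,
    selected_mask: np.ndarray,
    affine: np.ndarray,
    class_volumes: Sequence[BrainVolume],
    min_extent: int = 100,
    connectivity: int = 26,
) -> VoxelClusterReport:
    """Extract, localize, and direction-label one class's clusters."""
    grids = [v.data if isinstance(v, BrainVolume) else np.asarray(v) for v in class_volumes]
    mean_rel = np.mean(grids, axis=0) if grids else None
    clusters = extract_clusters(selected_mask, min_extent=min_extent, connectivity=connectivity)
    for c in clusters:
        localize_cluster(c, affine, mean_relative_volume=mean_rel)
        if grids:
            cluster_direction(c, grids)
    return VoxelClusterReport(class_id=class_id, clusters=clusters)
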