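"""Shared voxel-grid metadata and the scalar-map container.

All phantom subjects live on one common grid, which stands in for a cohort
that has already been normalized to a stereotaxic standard space.  World
coordinates are millimetres; the affine maps voxel indices ``(i, j, k)`` to
world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class Grid:
    """A regular 3-D voxel grid: shape, voxel size (mm) and affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape).transpose(1, 2, 3, 0).astype(float)
        return idx * np.asarray(self.voxel_size)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        return np.asarray(points_mm, float) / np.asarray(self.voxel_size)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * np.asarray(self.voxel_size)


@dataclass
class ScalarMap:
    """A voxel-wise scalar image (FA, MD, a correction field ...) on a grid."""

    data: np.ndarray
    grid: Grid
    name: str = ""
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.float32), self.grid.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, name: str = "") -> "ScalarMap":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        grid = Grid(tuple(int(s) for s in img.shape[:3]), vox)
        return cls(np.asarray(img.get_fdata()), grid, name=name)


def save_volume(data: np.ndarray, grid: Grid, path) -> None:
    """Write an arbitrary 3-D/4-D array as NIfTI-1 with the grid affine."""
    nib.save(nib.Nifti1Image(np.asarray(data), grid.affine), str(path))
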