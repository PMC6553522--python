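"""Voxel-grid and VOI containers plus NIfTI round-trip helpers.

Images are 3D arrays of uptake in %ID/g on an isotropic lattice; the
analysis assumes isotropic voxels, so anisotropic NIfTI input is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

_ISO_RTOL = 1e-3


@dataclass
class VoxelGrid:
    """3D uptake image in %ID/g with isotropic voxel spacing in mm."""

    values: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0 mm, got {self.spacing}")
        if self.values.min() < -1e-9:
            raise ValueError("uptake values must be >= 0 %ID/g")
        np.clip(self.values, 0.0, None, out=self.values)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing) ** 3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class TumorVOI:
    """Delineated tumor voxel set: coordinates, uptake values, spacing."""

    coords: np.ndarray  # (N, 3) int voxel indices
    values: np.ndarray  # (N,) uptake in %ID/g
    spacing: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.coords) == 0:
            raise ValueError("VOI must be nonempty")
        if len(self.values) != len(self.coords):
            raise ValueError("one value per coordinate required")
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) != len(self.coords):
            raise ValueError("VOI coordinates must be unique")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0 mm, got {self.spacing}")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def volume_mm3(self) -> float:
        """Metabolically active volume: voxel count x voxel volume."""
        return len(self) * float(self.spacing) ** 3

    def to_dense(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mask, value grid, offset) over the VOI bounding box."""
        offset = self.coords.min(axis=0)
        shape = self.coords.max(axis=0) - offset + 1
        mask = np.zeros(shape, dtype=bool)
        vals = np.zeros(shape, dtype=float)
        idx = tuple((self.coords - offset).T)
        mask[idx] = True
        vals[idx] = self.values
        return mask, vals, offset


def voi_from_mask(grid: VoxelGrid, mask: np.ndarray) -> TumorVOI:
    """Build a TumorVOI from a boolean mask over ``grid``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise ValueError("mask shape must match grid shape")
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValueError("mask selects no voxels")
    return TumorVOI(coords=coords, values=grid.values[mask], spacing=grid.spacing)


def _affine(spacing: float, origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def write_image(grid: VoxelGrid, path: str) -> None:
    """Write a VoxelGrid as a NIfTI-1 volume (float64, isotropic affine)."""
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid.spacing, grid.origin))
    img.header.set_zooms((grid.spacing,) * 3)
    nib.save(img, path)


def write_mask(mask: np.ndarray, spacing: float, path: str,
               origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    """Write an integer label map as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(mask).astype(np.int16), _affine(spacing, origin))
    img.header.set_zooms((spacing,) * 3)
    nib.save(img, path)


def read_image(path: str) -> VoxelGrid:
    """Read a NIfTI-1 volume; reject anisotropic spacing."""
    img = nib.load(path)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sp = zooms[0]
    if any(abs(z - sp) > _ISO_RTOL * sp for z in zooms):
        raise ValueError(f"anisotropic voxel spacing {zooms}; isotropic input required")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(values=data, spacing=sp, origin=origin)


def read_mask(path: str) -> tuple[np.ndarray, float]:
    """Read a NIfTI label map; returns (integer array, spacing)."""
    img = nib.load(path)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sp = zooms[0]
    if any(abs(z - sp) > _ISO_RTOL * sp for z in zooms):
        raise ValueError(f"anisotropic voxel spacing {zooms}; isotropic input required")
    return np.asarray(img.dataobj).astype(int), sp
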