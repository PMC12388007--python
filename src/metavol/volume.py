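"""In-memory containers for SUV volumes and region-of-interest masks.

A :class:`SUVVolume` is a 3-D grid of standardized-uptake values indexed
``(z, y, x)`` together with its voxel spacing in millimetres. World
coordinates of a voxel centre are ``origin_mm + index * spacing_mm`` per
axis. An :class:`ROIMask` is a boolean grid aligned voxel-for-voxel with
its volume.

NIfTI-1 is the on-disk format (via nibabel). Files are written with a
diagonal affine (spacing on the diagonal, origin in the translation
column); oblique or sheared affines are rejected on read because the
grid-aligned voxel-volume arithmetic used throughout would be wrong for
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "ROIMask", "GeometryError"]


class GeometryError(ValueError):
    """Volume/mask geometry mismatch or unsupported orientation."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive reals, got {spacing}")
    return spacing


@dataclass
class SUVVolume:
    """3-D standardized-uptake-value grid.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        SUV at each voxel; must be finite.
    voxel_spacing_mm : (dz, dy, dx)
        Voxel edge lengths in mm, all strictly positive.
    origin_mm : (z0, y0, x0)
        World position of voxel (0, 0, 0), mm.
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must all be finite")
        self.voxel_spacing_mm = _check_spacing(self.voxel_spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= product of spacings / 1000)."""
        dz, dy, dx = self.voxel_spacing_mm
        return dz * dy * dx / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (0=z, 1=y, 2=x)."""
        n = self.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.voxel_spacing_mm[axis]

    def to_nifti(self, path: str | Path) -> None:
        _write_nifti(self.values, self.voxel_spacing_mm, self.origin_mm, path)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "SUVVolume":
        values, spacing, origin = _read_nifti(path)
        return cls(values, spacing, origin)


@dataclass
class ROIMask:
    """Boolean voxel mask aligned with a :class:`SUVVolume`."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.values.ndim}")
        self.voxel_spacing_mm = _check_spacing(self.voxel_spacing_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_paired(self, volume: SUVVolume) -> None:
        """Raise :class:`GeometryError` unless mask and volume share geometry."""
        if self.shape != volume.shape:
            raise GeometryError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.voxel_spacing_mm, volume.voxel_spacing_mm):
            raise GeometryError(
                f"mask spacing {self.voxel_spacing_mm} != volume spacing "
                f"{volume.voxel_spacing_mm}"
            )

    def to_nifti(self, path: str | Path) -> None:
        _write_nifti(self.values.astype(np.uint8), self.voxel_spacing_mm, self.origin_mm, path)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ROIMask":
        values, spacing, origin = _read_nifti(path)
        return cls(values > 0.5, spacing, origin)


# NIfTI stores arrays (x, y, z); the in-memory convention here is (z, y, x).

def _write_nifti(values_zyx, spacing_zyx, origin_zyx, path) -> None:
    dz, dy, dx = spacing_zyx
    z0, y0, x0 = origin_zyx
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [x0, y0, z0]
    img = nib.Nifti1Image(np.ascontiguousarray(np.transpose(values_zyx, (2, 1, 0))), affine)
    nib.save(img, str(path))


def _read_nifti(path):
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise GeometryError(
            f"{path}: only axis-aligned (diagonal-affine) NIfTI volumes are supported"
        )
    spacing_xyz = np.abs(np.diag(rot))
    if np.any(spacing_xyz <= 0):
        raise GeometryError(f"{path}: non-positive voxel spacing in affine")
    values = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return values, spacing, origin
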