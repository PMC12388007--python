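"""Digital PET phantoms with analytically known MTV and HI2.

Each phantom is a 3-D SUV grid containing one (or more) ellipsoidal
lesions with a radially linear uptake profile and one uniform ellipsoidal
liver reference region, all embedded in a uniform background, with
optional additive Gaussian noise.

The radial-linear profile is what makes the phantom useful as an oracle:
at normalized ellipsoidal radius r in [0, 1] the noise-free uptake is

    suv(r) = suv_core + (suv_rim - suv_core) * r,

so the volume with suv >= T is the ellipsoid scaled to the fractional
radius r*(T) = clamp((suv_core - T) / (suv_core - suv_rim), 0, 1) and

    MTV(T) = V_ellipsoid * r*(T)^3

in closed form (for a homogeneous lesion, suv_core == suv_rim, MTV(T) is
the full volume when suv_core >= T and 0 otherwise). The analytic HI2 for
the equally spaced threshold triple (2.5, 3.0, 3.5) is then
MTV(2.5) - MTV(3.5).

Noise is additive Gaussian on SUV (the phantom emulates a reconstructed
image, not raw counts), reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ROIMask, SUVVolume

__all__ = ["PhantomSpec", "LesionSpec", "PhantomGroundTruth", "generate_phantom"]


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: centre/semi-axes in mm, core and rim SUV."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv_core: float
    suv_rim: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"lesion semi-axes must be positive, got {self.radii_mm}")
        if self.suv_core <= 0 or self.suv_rim < 0:
            raise ValueError("suv_core must be > 0 and suv_rim >= 0")
        if self.suv_rim > self.suv_core:
            raise ValueError(
                f"uptake must decrease radially: suv_core ({self.suv_core}) "
                f"< suv_rim ({self.suv_rim})"
            )

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm)) / 1000.0

    def analytic_mtv_ml(self, threshold: float) -> float:
        """Closed-form metabolic volume at an absolute SUV threshold."""
        if self.suv_core == self.suv_rim:
            return self.volume_ml if self.suv_core >= threshold else 0.0
        r_star = np.clip((self.suv_core - threshold) / (self.suv_core - self.suv_rim), 0.0, 1.0)
        return self.volume_ml * float(r_star) ** 3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, uptake and noise parameters of a digital phantom."""

    grid_shape: tuple[int, int, int] = (60, 80, 80)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 0.5
    lesion_center_mm: tuple[float, float, float] = (60.0, 50.0, 50.0)
    lesion_radii_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    suv_core: float = 4.5
    suv_rim: float = 1.0
    liver_center_mm: tuple[float, float, float] = (60.0, 110.0, 110.0)
    liver_radii_mm: tuple[float, float, float] = (25.0, 25.0, 25.0)
    liver_suv: float = 2.3
    noise_sd: float = 0.0
    seed: int = 0
    extra_lesions: tuple[LesionSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background_suv and noise_sd must be non-negative")
        if self.liver_suv <= 0:
            raise ValueError("liver_suv must be positive")
        _ = self.lesions  # validates core/rim ordering and radii

    @property
    def lesions(self) -> tuple[LesionSpec, ...]:
        primary = LesionSpec(
            self.lesion_center_mm, self.lesion_radii_mm, self.suv_core, self.suv_rim
        )
        return (primary,) + tuple(self.extra_lesions)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Noise-free analytic targets for the phantom's lesion(s)."""

    lesions: tuple[LesionSpec, ...]

    @property
    def lesion_volume_ml(self) -> float:
        return sum(l.volume_ml for l in self.lesions)

    def analytic_mtv_ml(self, threshold: float) -> float:
        """Summed closed-form MTV at an SUV threshold (non-increasing in it)."""
        return sum(l.analytic_mtv_ml(threshold) for l in self.lesions)

    @property
    def analytic_hi2(self) -> float:
        """HI2 for thresholds (2.5, 3.0, 3.5): MTV(2.5) - MTV(3.5)."""
        return self.analytic_mtv_ml(2.5) - self.analytic_mtv_ml(3.5)


def _normalized_radius_sq(coords, center_mm, radii_mm):
    zz, yy, xx = coords
    cz, cy, cx = center_mm
    rz, ry, rx = radii_mm
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2


def _check_inside(name, center_mm, radii_mm, extent_mm) -> None:
    for axis, (c, r, e) in enumerate(zip(center_mm, radii_mm, extent_mm)):
        if c - r < 0 or c + r > e:
            raise ValueError(
                f"{name} extends outside the grid on axis {axis} "
                f"(centre {c} mm, semi-axis {r} mm, grid extent {e} mm)"
            )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[SUVVolume, ROIMask, ROIMask, PhantomGroundTruth]:
    """Build (SUV volume, lesion mask, liver mask, analytic ground truth).

    The lesion mask is the union of all lesion ellipsoids (voxel-centre
    membership); the liver mask is the liver ellipsoid. Lesions must lie
    fully inside the grid and must not overlap each other or the liver.
    """
    spacing = spec.voxel_spacing_mm
    shape = tuple(int(n) for n in spec.grid_shape)
    extent_mm = tuple(n * s for n, s in zip(shape, spacing))

    for i, les in enumerate(spec.lesions):
        _check_inside(f"lesion {i}", les.center_mm, les.radii_mm, extent_mm)
    _check_inside("liver region", spec.liver_center_mm, spec.liver_radii_mm, extent_mm)

    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")

    values = np.full(shape, float(spec.background_suv))
    lesion_mask = np.zeros(shape, dtype=bool)
    for i, les in enumerate(spec.lesions):
        r2 = _normalized_radius_sq(coords, les.center_mm, les.radii_mm)
        inside = r2 <= 1.0
        if np.any(inside & lesion_mask):
            raise ValueError(f"lesion {i} overlaps another lesion")
        r = np.sqrt(r2[inside])
        values[inside] = les.suv_core + (les.suv_rim - les.suv_core) * r
        lesion_mask |= inside

    liver_r2 = _normalized_radius_sq(coords, spec.liver_center_mm, spec.liver_radii_mm)
    liver_mask = liver_r2 <= 1.0
    if np.any(liver_mask & lesion_mask):
        raise ValueError("liver reference region overlaps a lesion")
    values[liver_mask] = spec.liver_suv

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        np.maximum(values, 0.0, out=values)  # SUV cannot be negative

    volume = SUVVolume(values, spacing)
    truth = PhantomGroundTruth(spec.lesions)
    return (
        volume,
        ROIMask(lesion_mask, spacing),
        ROIMask(liver_mask, spacing),
        truth,
    )
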