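"""SUV-based lesion quantification.

Implements the standard FDG-PET biomarkers measured inside a region of
interest: SUVmax, SUVmean, SUV standard deviation, SUVpeak (1-mL sphere
around the hottest voxel), metabolic tumor volume (MTV) at absolute SUV
thresholds, total lesion glycolysis (TLG), and the liver reference values
SUVmax_liver / SUVmean_liver.

Conventions (all configurable where they are parameters):

* MTV segmentation is inclusive: a voxel with SUV exactly equal to the
  threshold is counted.
* Thresholds are absolute SUV values; the defaults 2.5 / 3.0 / 3.5 are the
  common absolute-threshold triple for lymphoma MTV profiling.
* "SUV SD" is the sample standard deviation (n-1 denominator, SPSS
  convention); a single-voxel region has SD 0.
* SUVpeak averages over voxels whose *centres* fall inside a sphere of the
  given volume (default 1 mL, EANM-style) centred on the hottest masked
  voxel; the sphere may extend beyond the mask but not beyond the grid.
  Ties for the hottest voxel break to the lowest (z, y, x) index.
* Voxel membership everywhere is by voxel-centre containment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ROIMask, SUVVolume

__all__ = [
    "EmptyROIError",
    "LesionMetrics",
    "LiverReference",
    "compute_suv",
    "suv_stats",
    "suv_peak",
    "segment_mtv",
    "mtv_profile",
    "tlg",
    "liver_reference",
    "quantify_lesion",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (2.5, 3.0, 3.5)


class EmptyROIError(ValueError):
    """Raised when an operation requires a non-empty region of interest."""


@dataclass
class LiverReference:
    suvmax_liver: float
    suvmean_liver: float


@dataclass
class LesionMetrics:
    """Per-lesion (or per-patient, summed-lesion) imaging biomarker bundle."""

    suv_max: float
    suv_mean: float
    suv_sd: float
    suv_peak: float
    mtv_ml: dict[float, float]
    tlg: dict[float, float]
    hi1: float
    hi2: float
    liver: LiverReference | None = None


def compute_suv(
    activity_kbq_per_ml: np.ndarray,
    injected_dose_mbq: float,
    body_weight_kg: float,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
    origin_mm=(0.0, 0.0, 0.0),
) -> SUVVolume:
    """Body-weight SUV normalization of an activity-concentration map.

    SUV = C [kBq/mL] / (dose [MBq] / weight [kg]) with the unit conversion
    1 MBq = 1000 kBq and 1 kg of tissue ~ 1000 mL, which cancels to
    ``C * weight / dose``. The injected dose is assumed decay-corrected to
    scan time.
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    activity = np.asarray(activity_kbq_per_ml, dtype=float)
    if not np.all(np.isfinite(activity)) or np.any(activity < 0):
        raise ValueError("activity map must be finite and non-negative")
    suv = activity * body_weight_kg / injected_dose_mbq
    return SUVVolume(suv, voxel_spacing_mm, origin_mm)


def _masked_values(volume: SUVVolume, mask: ROIMask) -> np.ndarray:
    mask.check_paired(volume)
    vals = volume.values[mask.values]
    if vals.size == 0:
        raise EmptyROIError("region of interest contains no voxels")
    return vals


def suv_stats(volume: SUVVolume, mask: ROIMask) -> tuple[float, float, float]:
    """(SUVmax, SUVmean, sample SUV SD) over the masked voxels."""
    vals = _masked_values(volume, mask)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.max()), float(vals.mean()), sd


def suv_peak(volume: SUVVolume, mask: ROIMask, sphere_volume_ml: float = 1.0) -> float:
    """Mean SUV in a sphere of ``sphere_volume_ml`` centred on the hottest voxel."""
    if sphere_volume_ml <= 0:
        raise ValueError(f"sphere volume must be positive, got {sphere_volume_ml}")
    _masked_values(volume, mask)  # geometry + emptiness check
    vals = np.where(mask.values, volume.values, -np.inf)
    # np.argmax returns the first maximum in C order == lowest (z, y, x)
    hot = np.unravel_index(int(np.argmax(vals)), vals.shape)
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    dz, dy, dx = volume.voxel_spacing_mm
    # candidate index window around the hot voxel
    span = [int(np.floor(radius_mm / s)) for s in (dz, dy, dx)]
    sl = tuple(
        slice(max(0, h - w), min(n, h + w + 1))
        for h, w, n in zip(hot, span, volume.shape)
    )
    zz, yy, xx = np.meshgrid(
        (np.arange(sl[0].start, sl[0].stop) - hot[0]) * dz,
        (np.arange(sl[1].start, sl[1].stop) - hot[1]) * dy,
        (np.arange(sl[2].start, sl[2].stop) - hot[2]) * dx,
        indexing="ij",
    )
    inside = zz**2 + yy**2 + xx**2 <= radius_mm**2
    return float(volume.values[sl][inside].mean())


def segment_mtv(
    volume: SUVVolume, mask: ROIMask, threshold_suv: float
) -> tuple[float, ROIMask]:
    """Threshold-segment the lesion; returns (MTV in mL, segmented mask).

    A voxel belongs to the metabolic volume when it is inside the lesion
    mask and its SUV >= threshold (inclusive). An empty segmentation is a
    valid result (MTV 0), not an error.
    """
    if threshold_suv <= 0:
        raise ValueError(f"threshold must be positive, got {threshold_suv}")
    _masked_values(volume, mask)
    seg = mask.values & (volume.values >= threshold_suv)
    mtv_ml = float(seg.sum()) * volume.voxel_volume_ml
    return mtv_ml, ROIMask(seg, volume.voxel_spacing_mm, volume.origin_mm)


def mtv_profile(
    volume: SUVVolume,
    mask: ROIMask,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> dict[float, float]:
    """MTV at each threshold of a strictly increasing list (length >= 2)."""
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) < 2:
        raise ValueError("at least 2 thresholds required (the MTV slope needs them)")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
    return {t: segment_mtv(volume, mask, t)[0] for t in thresholds}


def tlg(volume: SUVVolume, mask: ROIMask, threshold_suv: float) -> float:
    """Total lesion glycolysis: mean SUV of the segmented voxels times MTV."""
    mtv_ml, seg = segment_mtv(volume, mask, threshold_suv)
    if seg.n_voxels == 0:
        return 0.0
    mean_seg = float(volume.values[seg.values].mean())
    return mean_seg * mtv_ml


def liver_reference(volume: SUVVolume, liver_roi: ROIMask) -> LiverReference:
    """SUVmax and SUVmean over a normal-liver reference region."""
    vals = _masked_values(volume, liver_roi)
    return LiverReference(float(vals.max()), float(vals.mean()))


def quantify_lesion(
    volume: SUVVolume,
    lesion: ROIMask,
    liver: ROIMask | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    sphere_volume_ml: float = 1.0,
) -> LesionMetrics:
    """Full biomarker bundle for one lesion mask (plus optional liver ROI)."""
    from .heterogeneity import hi1 as _hi1, hi2 as _hi2, ThresholdMTVSeries

    smax, smean, ssd = suv_stats(volume, lesion)
    peak = suv_peak(volume, lesion, sphere_volume_ml)
    profile = mtv_profile(volume, lesion, thresholds)
    tlgs = {t: tlg(volume, lesion, t) for t in profile}
    h1 = _hi1(ssd, smean) if smean > 0 else float("nan")
    h2 = _hi2(ThresholdMTVSeries(tuple(profile.items())))
    liv = liver_reference(volume, liver) if liver is not None else None
    return LesionMetrics(
        suv_max=smax,
        suv_mean=smean,
        suv_sd=ssd,
        suv_peak=peak,
        mtv_ml=profile,
        tlg=tlgs,
        hi1=h1,
        hi2=h2,
        liver=liv,
    )
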