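"""Intratumoral heterogeneity indices derived from SUV statistics.

Two indices are implemented:

HI1
    The coefficient of variation of uptake inside the lesion: SUV standard
    deviation divided by SUVmean. Dimensionless, scale-invariant.

HI2
    The negative slope of the ordinary-least-squares line through the
    (threshold, MTV) points of a threshold-MTV profile. Units are mL per
    SUV unit. A lesion whose metabolic volume collapses quickly as the
    threshold rises (steep gradient between core and rim) has a large HI2.
    For the default equally spaced thresholds (2.5, 3.0, 3.5) the OLS
    slope reduces to a closed form and HI2 == MTV(2.5) - MTV(3.5) exactly,
    independent of the middle point.

HI2 can be negative for non-monotone noisy profiles; it is reported as-is
(no clamping), since clamping would bias downstream ROC cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quant import DEFAULT_THRESHOLDS, mtv_profile, suv_stats
from .volume import ROIMask, SUVVolume

__all__ = ["ThresholdMTVSeries", "hi1", "hi2", "hi_profile"]


@dataclass(frozen=True)
class ThresholdMTVSeries:
    """Ordered (threshold_suv, mtv_ml) pairs; thresholds strictly increasing."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a threshold-MTV series needs at least 2 points")
        ts = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {ts}")
        if any(p[1] < 0 for p in self.points):
            raise ValueError("MTV values must be non-negative")


def hi1(suv_sd: float, suv_mean: float) -> float:
    """Coefficient of variation: SUV SD / SUVmean."""
    if suv_mean <= 0:
        raise ValueError(f"SUVmean must be positive for HI1, got {suv_mean}")
    if suv_sd < 0:
        raise ValueError(f"SUV SD must be non-negative, got {suv_sd}")
    return suv_sd / suv_mean


def hi2(series: ThresholdMTVSeries) -> float:
    """Negative OLS slope of MTV against SUV threshold (mL per SUV unit)."""
    t = np.array([p[0] for p in series.points])
    v = np.array([p[1] for p in series.points])
    tc = t - t.mean()
    slope = (tc * (v - v.mean())).sum() / (tc * tc).sum()
    return float(-slope)


def hi_profile(
    volume: SUVVolume,
    mask: ROIMask,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> tuple[float, float]:
    """(HI1, HI2) for a lesion: CV over the full mask, slope of its MTV profile."""
    _, smean, ssd = suv_stats(volume, mask)
    profile = mtv_profile(volume, mask, thresholds)
    return hi1(ssd, smean), hi2(ThresholdMTVSeries(tuple(profile.items())))
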