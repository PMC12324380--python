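"""Particle mass estimation from class-average pixel intensities.

In a normalized 2D class average the integrated particle signal above
background is approximately proportional to the projected molecular mass.
The estimator:

1. segments the particle as all pixels more than 3 standard deviations above
   the image mean (remainder = background),
2. subtracts the background mean from each particle pixel,
3. sums the background-subtracted particle intensities and multiplies by the
   pixel size squared (A^2), giving an intensity proxy in intensity * A^2,
4. converts the proxy to kDa with a linear, through-origin calibration factor
   fitted on particles of known mass.

The three mass-deviation features fed to the quality scorer are the
deviations of one class's mass from the mean, median and mode of all class
masses in the same classification job. The mode of a continuous sample is
taken as the half-sample mode (Bickel & Fruehwirth's robust estimator),
falling back to the median for fewer than 3 samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "MassCalibration",
    "MassFeatures",
    "segment_particle",
    "summed_intensity",
    "estimate_mass",
    "fit_calibration",
    "mass_features",
    "half_sample_mode",
]


@dataclass(frozen=True)
class MassCalibration:
    """Fitted intensity -> kDa conversion.

    ``slope`` is the calibration factor in kDa per (intensity * A^2);
    ``fit_r2`` is the coefficient of determination of the through-origin fit;
    ``n_points`` the number of calibration particles.
    """

    slope: float
    fit_r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"calibration slope must be > 0, got {self.slope}")
        if self.n_points < 2:
            raise ValidationError("calibration needs at least 2 points")

    def to_kda(self, summed: float | np.ndarray) -> float | np.ndarray:
        """Convert a summed intensity (intensity * A^2) to kDa."""
        return self.slope * summed


@dataclass(frozen=True)
class MassFeatures:
    """One class's mass and its deviations from the job-wide mass statistics."""

    mass_kda: float
    dev_mean: float
    dev_median: float
    dev_mode: float


def segment_particle(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an image into particle and background masks by 3-sigma threshold.

    Particle pixels are those strictly above ``mean(image) + 3 * sd(image)``,
    with mean and sd taken over the whole image; the background mask is the
    complement, so the two masks partition the image. A constant image has an
    empty particle mask (sd = 0 and no pixel exceeds the mean).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size < 2:
        raise ValidationError("image must have at least 2 pixels")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    threshold = image.mean() + 3.0 * image.std()
    particle = image > threshold
    return particle, ~particle


def summed_intensity(image: np.ndarray, pixel_size: float) -> float:
    """Background-subtracted particle intensity sum, scaled by pixel area.

    Returns ``sum_over_particle(pixel - mean(background)) * pixel_size**2``
    in intensity * A^2; 0.0 when the particle mask is empty. The background
    subtraction makes the result invariant to additive intensity offsets.
    """
    if pixel_size <= 0:
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    image = np.asarray(image, dtype=np.float64)
    particle, background = segment_particle(image)
    n_particle = int(particle.sum())
    if n_particle == 0:
        return 0.0
    bg_mean = image[background].mean() if background.any() else 0.0
    return float((image[particle] - bg_mean).sum() * pixel_size**2)


def estimate_mass(
    image: np.ndarray, pixel_size: float, calibration: MassCalibration
) -> float:
    """Estimate a class average's particle mass in kDa."""
    return float(calibration.to_kda(summed_intensity(image, pixel_size)))


def fit_calibration(points: Sequence[tuple[float, float]]) -> MassCalibration:
    """Fit the through-origin line mass = slope * intensity.

    ``points`` are (summed_intensity, known_mass_kda) pairs, all strictly
    positive. The closed-form least-squares slope is sum(x*y) / sum(x^2);
    ``fit_r2`` is 1 - RSS/TSS with TSS about the mass mean.
    """
    if len(points) < 2:
        raise InsufficientDataError(
            f"calibration needs >= 2 points, got {len(points)}"
        )
    x = np.asarray([p[0] for p in points], dtype=np.float64)
    y = np.asarray([p[1] for p in points], dtype=np.float64)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("calibration intensities and masses must be > 0")
    slope = float((x * y).sum() / (x * x).sum())
    residuals = y - slope * x
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((residuals**2).sum()) / tss if tss > 0 else 1.0
    return MassCalibration(slope=slope, fit_r2=max(min(r2, 1.0), 0.0), n_points=len(points))


def half_sample_mode(values: np.ndarray) -> float:
    """Robust mode of a continuous sample (half-sample mode).

    Recursively keeps the half-width window containing the most points; for
    n < 3 the median is returned (the mode of so few points is undefined).
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    while v.size >= 3:
        half = (v.size + 1) // 2
        widths = v[half - 1 :] - v[: v.size - half + 1]
        v = v[np.argmin(widths) : np.argmin(widths) + half]
        if widths.min() == 0:
            return float(v[0])
    return float(np.median(v))


def mass_features(masses: Sequence[float], target_index: int) -> MassFeatures:
    """Deviations of one class's mass from the job-wide mean/median/mode.

    The deviations are signed (positive = heavier than the job's typical
    class); over all classes the dev_mean values sum to zero by construction.
    """
    if len(masses) == 0:
        raise ValidationError("masses must be non-empty")
    if not 0 <= target_index < len(masses):
        raise ValidationError(
            f"target_index {target_index} out of range for {len(masses)} masses"
        )
    m = np.asarray(masses, dtype=np.float64)
    target = float(m[target_index])
    return MassFeatures(
        mass_kda=target,
        dev_mean=target - float(m.mean()),
        dev_median=target - float(np.median(m)),
        dev_mode=target - half_sample_mode(m),
    )
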