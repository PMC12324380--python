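"""Synthetic graded class averages, metadata and mock classification backends.

Real training corpora for a 2D-class quality scorer are expert-labeled and
enormous; this module emulates their structure so every part of the package
is testable offline:

* **Phantoms** are Gaussian-blob mixtures (a handful of blobs near the image
  center), standing in for projections of a particle. Each class carries a
  quality grade 1 (best) ... 5 (unusable) which controls a low-pass cutoff
  (worse grade = stronger blur) and an additive Gaussian noise level (worse
  grade = more noise) — the same monotone degradation an expert grades real
  class averages by.
* Each class average is the mean of two independently noised half-images,
  so a Fourier ring correlation between the halves yields a plausible
  resolution estimate (0.143 threshold, the community convention).
* Class distributions are a seeded Dirichlet draw (summing to 1); masses
  come from the mass estimator applied to the clean phantom.
* Mock classification backends and scripted scorers exercise the selection
  workflow without any real classification engine.

CTF effects, beam-induced motion and picking artifacts are deliberately not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import ClassAverageStack, ClassRecord, ScoreTable
from .mass import summed_intensity
from .workflow import ClassificationResult

__all__ = [
    "SyntheticSpec",
    "generate_stack",
    "generate_calibration_set",
    "mock_backend",
    "round_robin_rule",
    "scripted_scorer",
    "frc_resolution",
    "DEFAULT_NOISE_BY_GRADE",
    "DEFAULT_BLUR_BY_GRADE",
]

# additive Gaussian noise sd (in units of blob amplitude ~1) per grade:
# a geometric ladder spanning SNR ~25 (grade 1, sharp) to ~0.1 (grade 5,
# unusable), so grades separate in both appearance and FRC resolution
DEFAULT_NOISE_BY_GRADE = {1: 0.04, 2: 0.16, 3: 0.64, 4: 2.5, 5: 10.0}
# low-pass cutoff as a fraction of Nyquist per grade (lower = blurrier)
DEFAULT_BLUR_BY_GRADE = {1: 0.90, 2: 0.70, 3: 0.50, 4: 0.35, 5: 0.20}

# nominal intensity->kDa factor for synthetic masses (kDa per intensity*A^2)
NOMINAL_CALIBRATION_SLOPE = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic graded dataset; regeneration is bit-identical.

    ``phantom`` optionally fixes one blob mixture — rows of
    (center_y, center_x, sigma, amplitude) in pixel units — shared by all
    classes; by default each class draws its own phantom from the seed.
    """

    n_classes: int = 50
    grade_assignment: Optional[tuple[int, ...]] = None  # default: cycle 1..5
    image_side: int = 64
    pixel_size: float = 1.5
    phantom: Optional[tuple[tuple[float, float, float, float], ...]] = None
    noise_sd_by_grade: dict = field(
        default_factory=lambda: dict(DEFAULT_NOISE_BY_GRADE)
    )
    blur_by_grade: dict = field(default_factory=lambda: dict(DEFAULT_BLUR_BY_GRADE))
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.image_side < 8:
            raise ValidationError("need n_classes >= 1 and image_side >= 8")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        grades = sorted(self.noise_sd_by_grade)
        noise = [self.noise_sd_by_grade[g] for g in grades]
        blur = [self.blur_by_grade[g] for g in grades]
        if any(b > a for a, b in zip(noise[1:], noise)) or any(
            a < b for a, b in zip(blur, blur[1:])
        ):
            raise ValidationError(
                "noise must be non-decreasing and blur cutoff non-increasing in grade"
            )

    @property
    def grades(self) -> list[int]:
        if self.grade_assignment is not None:
            if len(self.grade_assignment) != self.n_classes:
                raise ValidationError("grade_assignment length != n_classes")
            return list(self.grade_assignment)
        return [(i % 5) + 1 for i in range(self.n_classes)]


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------


def _draw_phantom_params(rng: np.random.Generator, side: int):
    # ranges kept narrow so the grade (noise/blur), not phantom-to-phantom
    # variability, dominates image quality and the FRC estimate
    n_blobs = int(rng.integers(3, 6))
    params = []
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.38 * side, 0.62 * side, size=2)
        sigma = rng.uniform(side / 12, side / 8)
        amp = rng.uniform(0.8, 1.2)
        params.append((cy, cx, sigma, amp))
    return tuple(params)


def _render_phantom(params, side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    img = np.zeros((side, side))
    for cy, cx, sigma, amp in params:
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return img


def _lowpass(image: np.ndarray, cutoff_frac: float) -> np.ndarray:
    """Soft radial low-pass at ``cutoff_frac`` of Nyquist (8th-order rolloff)."""
    n = image.shape[0]
    f = np.fft.fftfreq(n)  # cycles/pixel, Nyquist = 0.5
    fr = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    fc = 0.5 * cutoff_frac
    mask = 1.0 / (1.0 + (fr / fc) ** 8)
    return np.fft.ifft2(np.fft.fft2(image) * mask).real


def frc_resolution(
    half1: np.ndarray, half2: np.ndarray, pixel_size: float, threshold: float = 0.143
) -> float:
    """Resolution (A) where the Fourier ring correlation drops below threshold.

    The FRC between two half-images is computed over integer-frequency
    rings; the first crossing below ``threshold`` is linearly interpolated.
    If the correlation never drops that low the Nyquist resolution
    (2 * pixel_size) is returned.
    """
    n = half1.shape[0]
    f1 = np.fft.fftshift(np.fft.fft2(half1))
    f2 = np.fft.fftshift(np.fft.fft2(half2))
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2).astype(int)
    n_rings = n // 2
    num = np.bincount(r.ravel(), (f1 * np.conj(f2)).real.ravel(), n_rings)
    p1 = np.bincount(r.ravel(), np.abs(f1).ravel() ** 2, n_rings)
    p2 = np.bincount(r.ravel(), np.abs(f2).ravel() ** 2, n_rings)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(p1 * p2)
    frc[0] = 1.0
    frc = np.nan_to_num(frc)
    # 5-ring moving average stabilizes the crossing point on small images
    smoothed = frc.copy()
    for ring in range(1, n_rings):
        lo, hi = max(0, ring - 2), min(n_rings, ring + 3)
        smoothed[ring] = frc[lo:hi].mean()
    frc = smoothed
    for ring in range(1, n_rings):
        if frc[ring] < threshold:
            lo, hi = frc[ring - 1], frc[ring]
            frac = (lo - threshold) / (lo - hi) if lo != hi else 0.0
            radius = (ring - 1) + frac
            radius = max(radius, 1e-6)
            return float(n * pixel_size / radius)
    return 2.0 * pixel_size


def generate_stack(spec: SyntheticSpec) -> tuple[ClassAverageStack, list[ClassRecord]]:
    """Generate a graded synthetic stack plus fully populated metadata.

    Each class image is the mean of two half-images (filtered phantom +
    independent noise at sd * sqrt(2) each), so the returned
    ``frc_resolution`` is estimated exactly the way half-set resolutions are
    estimated in practice. Records carry the ground-truth grade as ``label``.
    """
    master = np.random.default_rng(spec.seed)
    distribution = master.dirichlet(np.ones(spec.n_classes))
    grades = spec.grades
    images, records = [], []
    for i, grade in enumerate(grades):
        rng = np.random.default_rng([spec.seed, i])
        params = spec.phantom if spec.phantom is not None else _draw_phantom_params(
            rng, spec.image_side
        )
        clean = _lowpass(
            _render_phantom(params, spec.image_side), spec.blur_by_grade[grade]
        )
        sd = spec.noise_sd_by_grade[grade]
        noise_shape = (2, spec.image_side, spec.image_side)
        halves = clean[None] + rng.standard_normal(noise_shape) * sd * np.sqrt(2.0)
        image = halves.mean(axis=0)
        images.append(image.astype(np.float32))
        res = frc_resolution(halves[0], halves[1], spec.pixel_size)
        mass = NOMINAL_CALIBRATION_SLOPE * summed_intensity(clean, spec.pixel_size)
        records.append(
            ClassRecord(
                class_index=i,
                image_ref=("synthetic", i),
                pixel_size=spec.pixel_size,
                frc_resolution=res,
                class_distribution=float(distribution[i]),
                mass_kda=mass,
                label=float(grade),
            )
        )
    stack = ClassAverageStack(
        images=np.stack(images), pixel_size=spec.pixel_size, source_path="synthetic"
    )
    return stack, records


def generate_calibration_set(
    n: int, slope: float, noise_rel: float, seed: int = 0
) -> list[tuple[float, float]]:
    """Synthetic (summed_intensity, known_mass_kda) calibration pairs.

    Intensities are log-uniform over two decades (1e2..1e4 intensity*A^2);
    masses are slope * intensity perturbed by multiplicative Gaussian noise
    of relative sd ``noise_rel``.
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 calibration points, got {n}")
    rng = np.random.default_rng(seed)
    intensities = 10.0 ** rng.uniform(2.0, 4.0, size=n)
    masses = slope * intensities * (1.0 + noise_rel * rng.standard_normal(n))
    return list(zip(intensities.tolist(), masses.tolist()))


# ---------------------------------------------------------------------------
# workflow test doubles
# ---------------------------------------------------------------------------


def round_robin_rule(n_classes: int):
    """Assignment rule dealing sorted particle ids into ``n_classes`` groups."""

    def rule(ids: Sequence[int], iteration: int, seed: int) -> dict[int, list[int]]:
        groups: dict[int, list[int]] = {k: [] for k in range(n_classes)}
        for j, pid in enumerate(sorted(ids)):
            groups[j % n_classes].append(pid)
        return {k: v for k, v in groups.items() if v}

    return rule


def mock_backend(assignment_rule: Callable, pixel_size: float = 1.0):
    """Wrap an assignment rule as a classification backend.

    The rule maps (particle ids, iteration, seed) to a dict
    ``{class_index: member ids}``; the backend packages that as a
    :class:`ClassificationResult` with placeholder metadata and verifies the
    partition contract.
    """

    def backend(ids: Sequence[int], iteration: int, seed: int) -> ClassificationResult:
        groups = assignment_rule(ids, iteration, seed)
        total = sum(len(v) for v in groups.values())
        classes = [
            (
                None,
                list(members),
                ClassRecord(
                    class_index=idx,
                    pixel_size=pixel_size,
                    frc_resolution=10.0,
                    class_distribution=len(members) / max(total, 1),
                ),
            )
            for idx, members in sorted(groups.items())
        ]
        result = ClassificationResult(classes)
        result.validate_partition(set(ids))
        return result

    return backend


def scripted_scorer(scores_by_call: Sequence[dict[int, float] | float]):
    """A scorer whose output follows a script, one entry per invocation.

    Each entry is either one number (every class gets that score) or a dict
    mapping class_index to score; the last entry repeats if the workflow
    calls the scorer more often than the script is long.
    """
    call_count = {"n": 0}

    def scorer(result: ClassificationResult) -> ScoreTable:
        i = min(call_count["n"], len(scores_by_call) - 1)
        call_count["n"] += 1
        entry = scores_by_call[i]
        indices = [rec.class_index for _, _, rec in result.classes]
        if isinstance(entry, dict):
            scores = [float(entry[idx]) for idx in indices]
        else:
            scores = [float(entry)] * len(indices)
        return ScoreTable(
            class_indices=indices,
            image_refs=[("mock", idx) for idx in indices],
            scores=scores,
        )

    return scorer
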