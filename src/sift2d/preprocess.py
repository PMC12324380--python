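"""Canonicalization of class averages to the scorer's 210x210 input frame.

2D class averages arrive at arbitrary (square) box sizes. The scorer's
canonical frame is 210x210 pixels:

* images smaller than 210 (but at least 31x31) are zero-padded, centered;
* images larger than 210 are Fourier-cropped: the discrete Fourier transform
  is truncated symmetrically around DC to the new band limit, which
  downsamples while preserving low-frequency content exactly (the standard
  cryo-EM downsampling);
* a 210x210 image passes through untouched.

Fourier cropping rescales amplitudes so the image mean (DC term) — and with
it each retained mode's amplitude — is preserved. Intensity normalization to
zero mean / unit variance is applied after canonicalization, so padded zeros
participate in the statistics deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["CANONICAL_SIDE", "MIN_SIDE", "CanonicalImage", "canonicalize", "normalize", "fourier_crop"]

CANONICAL_SIDE = 210
MIN_SIDE = 31


@dataclass(frozen=True)
class CanonicalImage:
    """A class average brought to the canonical frame.

    ``scale_action`` records what happened: ``identity``, ``padded`` or
    ``fourier_downsampled``. For padded images the original occupies a
    centered window and everything outside it is exactly zero.
    """

    pixels: np.ndarray
    original_shape: tuple[int, int]
    scale_action: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (CANONICAL_SIDE, CANONICAL_SIDE):
            raise ValidationError(
                f"canonical image must be {CANONICAL_SIDE}x{CANONICAL_SIDE}, "
                f"got {self.pixels.shape}"
            )


def fourier_crop(image: np.ndarray, out_side: int) -> np.ndarray:
    """Downsample a square image by truncating its Fourier spectrum.

    Keeps the ``out_side`` x ``out_side`` window of spatial frequencies
    centered on DC and discards everything above the new Nyquist limit.
    Amplitudes are rescaled by (out_side / in_side)^2 so the mean and each
    surviving mode's amplitude are unchanged.
    """
    n = image.shape[0]
    if out_side > n:
        raise ValidationError("fourier_crop cannot upsample")
    if out_side == n:
        return image.astype(np.float64, copy=True)
    spectrum = np.fft.fftshift(np.fft.fft2(image.astype(np.float64)))
    c = n // 2
    lo, hi = c - out_side // 2, c + (out_side + 1) // 2
    cropped = spectrum[lo:hi, lo:hi]
    out = np.fft.ifft2(np.fft.ifftshift(cropped)) * (out_side**2 / n**2)
    return np.ascontiguousarray(out.real)


def canonicalize(image: np.ndarray) -> CanonicalImage:
    """Bring a square class-average image to the canonical 210x210 frame.

    Raises a size error for sides below 31 pixels and a shape error for
    non-square input (class averages are square on every mainstream
    platform; silently reshaping would mask upstream coordinate bugs).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValidationError(
            f"class averages must be square 2D images, got shape {image.shape}"
        )
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    side = image.shape[0]
    if side < MIN_SIDE:
        raise ValidationError(
            f"image side {side} px is below the {MIN_SIDE}x{MIN_SIDE} px minimum"
        )
    if side == CANONICAL_SIDE:
        return CanonicalImage(image.copy(), (side, side), "identity")
    if side < CANONICAL_SIDE:
        # centered; an odd size difference puts the extra row/column at the
        # bottom/right
        before = (CANONICAL_SIDE - side) // 2
        after = CANONICAL_SIDE - side - before
        padded = np.pad(image, ((before, after), (before, after)))
        return CanonicalImage(padded, (side, side), "padded")
    return CanonicalImage(
        fourier_crop(image, CANONICAL_SIDE), (side, side), "fourier_downsampled"
    )


def normalize(image: np.ndarray) -> np.ndarray:
    """Standardize an image to zero mean and unit standard deviation.

    A constant image maps to all zeros. Idempotent: normalizing an already
    normalized image returns it unchanged (up to float rounding).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    sd = image.std()
    if sd == 0:
        return np.zeros_like(image)
    return (image - image.mean()) / sd
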