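"""Detector model: PSF blur, Poisson shot noise, integer quantization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class DetectorModel:
    """Gaussian PSF + Poisson counting + fixed-depth integer output.

    psf_sigma: blur width in pixels (also absorbs source-size/coherence blur).
    photons_per_pixel: expected counts at unit intensity; set ``noise=False``
        to disable the Poisson stage.
    bit_depth: output integer depth; images are min-max scaled per frame.
    """

    psf_sigma: float = 0.6
    photons_per_pixel: float = 5.0e4
    bit_depth: int = 16
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.noise and not self.photons_per_pixel > 0:
            raise ValueError("photons_per_pixel must be positive when noise is enabled")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class ProjectionImage:
    """Detected 2-D intensity grid with acquisition metadata."""

    pixels: np.ndarray
    pixel_size_m: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def blur(intensity: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Normalized Gaussian PSF (total flux preserved; periodic boundaries)."""
    if psf_sigma == 0:
        return intensity.copy()
    return gaussian_filter(intensity, sigma=psf_sigma, mode="wrap")


def sample_counts(
    intensity: np.ndarray, detector: DetectorModel, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel Poisson counts with mean photons_per_pixel * intensity."""
    return rng.poisson(detector.photons_per_pixel * intensity).astype(np.float64)


def quantize_to_depth(img: np.ndarray, bit_depth: int) -> np.ndarray:
    """Min-max scale to the full integer range of the given depth."""
    vmax = 2**bit_depth - 1
    lo, hi = float(img.min()), float(img.max())
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    if hi == lo:
        return np.zeros(img.shape, dtype=dtype)
    scaled = (img - lo) / (hi - lo) * vmax
    return np.round(scaled).astype(dtype)


def detect(
    intensity: np.ndarray,
    detector: DetectorModel,
    pixel_size_m: float = 9e-6,
    rng: np.random.Generator | None = None,
) -> ProjectionImage:
    """Apply the detector chain: blur -> Poisson counts -> integer image.

    With noise disabled the count stage is skipped and the blurred intensity
    is quantized directly.  The per-frame min/max used for scaling is kept
    in ``meta`` so quantization is invertible up to rounding.
    """
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    blurred = blur(intensity, detector.psf_sigma)
    if detector.noise:
        if rng is None:
            rng = np.random.default_rng(detector.seed)
        signal = sample_counts(blurred, detector, rng)
    else:
        signal = blurred
    pixels = quantize_to_depth(signal, detector.bit_depth)
    return ProjectionImage(
        pixels=pixels,
        pixel_size_m=pixel_size_m,
        meta={
            "psf_sigma": detector.psf_sigma,
            "photons_per_pixel": detector.photons_per_pixel,
            "noise": detector.noise,
            "scale_min": float(signal.min()),
            "scale_max": float(signal.max()),
        },
    )
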