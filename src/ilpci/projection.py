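"""Forward model: projected phase/absorption maps and free-space propagation.

Under plane-wave, monochromatic illumination the object reduces to a thin
transmission function q(x,y) = sqrt(I0) * exp(i*phi) with

    phi(x,y) = -k * sum_m delta_m * t_m(x,y)
    I0(x,y)  = exp(-2k * sum_m beta_m * t_m(x,y))

where t_m is the projected thickness of material m.  Free-space propagation
over a distance z is applied in the Fourier domain with the paraxial Fresnel
transfer function

    H(u,v) = exp(i k z) * exp(-i pi lambda z (u^2 + v^2)),

and for weak objects in the near field the detected intensity linearizes to
the transport-of-intensity form

    I = I0 * (1 - (lambda z / 2 pi) * laplacian(phi)),

i.e. contrast proportional to the Laplacian of the phase — the familiar
edge enhancement of in-line phase-contrast images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .optics import OpticalConstants, PropagationGeometry

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomScene

logger = logging.getLogger(__name__)


@dataclass
class PhantomProjection:
    """Projected phase map (radians) and contact absorption image I0 in (0,1]."""

    phase: np.ndarray
    contact_intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.phase.shape != self.contact_intensity.shape:
            raise ValueError("phase and contact_intensity shapes differ")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class WaveField:
    """Complex scalar field sampled on a regular grid (unit incident amplitude)."""

    complex_amplitude: np.ndarray
    pixel_size_m: float

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.complex_amplitude) ** 2

    def total_intensity(self) -> float:
        return float(self.intensity.sum() * self.pixel_size_m**2)


def project_scene(
    scene: "PhantomScene | Mapping[str, np.ndarray]",
    optics: OpticalConstants,
) -> PhantomProjection:
    """Project a phantom's material thickness maps into (phase, I0).

    Accepts a :class:`~ilpci.phantom.PhantomScene` or a plain mapping
    material-name -> thickness map (meters).  Every material present must
    have (delta, beta) in ``optics``; zero thickness everywhere yields
    phi = 0 and I0 = 1.
    """
    thickness = scene.thickness_maps if hasattr(scene, "thickness_maps") else scene
    if not thickness:
        raise ValueError("scene has no thickness maps")
    k = optics.wave_number
    shape = next(iter(thickness.values())).shape
    phase = np.zeros(shape, dtype=float)
    mu_t = np.zeros(shape, dtype=float)
    for name, t in thickness.items():
        if t.shape != shape:
            raise ValueError(f"thickness map {name!r} has shape {t.shape}, expected {shape}")
        if np.any(t < 0):
            raise ValueError(f"negative thickness in material {name!r}")
        m = optics.material(name)
        phase -= k * m.delta * t
        mu_t += 2.0 * k * m.beta * t
    return PhantomProjection(phase=phase, contact_intensity=np.exp(-mu_t))


def projection_to_wavefield(
    projection: PhantomProjection, geometry: PropagationGeometry
) -> WaveField:
    """Exit wave q = sqrt(I0) * exp(i*phi) at the sample's back plane."""
    amp = np.sqrt(projection.contact_intensity) * np.exp(1j * projection.phase)
    return WaveField(complex_amplitude=amp, pixel_size_m=geometry.pixel_size_m)


def max_alias_free_distance(geometry: PropagationGeometry, optics: OpticalConstants) -> float:
    """Largest z for which the Fresnel chirp stays below a phase of pi at Nyquist."""
    u_max = 1.0 / (2.0 * geometry.pixel_size_m)
    return 1.0 / (optics.wavelength * u_max**2)


def fresnel_propagate(
    field: WaveField,
    geometry: PropagationGeometry,
    optics: OpticalConstants,
) -> WaveField:
    """Propagate a wavefield by geometry.distance_m with the paraxial
    Fresnel transfer function on the periodic FFT grid.

    z = 0 returns the field unchanged (the transfer function is unity).
    Warns when the chirp phase pi*lambda*z*u_max^2 exceeds pi at Nyquist
    (discrete chirp aliasing), reporting the maximum alias-free distance.
    """
    if field.complex_amplitude.shape != geometry.grid_shape:
        raise ValueError(
            f"field shape {field.complex_amplitude.shape} does not match "
            f"geometry grid {geometry.grid_shape}"
        )
    z = geometry.distance_m
    lam = optics.wavelength
    if z == 0.0:
        return WaveField(field.complex_amplitude.copy(), field.pixel_size_m)
    u_max = 1.0 / (2.0 * geometry.pixel_size_m)
    if np.pi * lam * z * u_max**2 > np.pi:
        warnings.warn(
            "Fresnel chirp aliases at Nyquist for z=%.3g m; maximum alias-free "
            "distance is %.3g m" % (z, max_alias_free_distance(geometry, optics)),
            RuntimeWarning,
            stacklevel=2,
        )
    u, v = geometry.frequency_grids()
    transfer = np.exp(1j * optics.wave_number * z) * np.exp(
        -1j * np.pi * lam * z * (u**2 + v**2)
    )
    spectrum = np.fft.fft2(field.complex_amplitude)
    out = np.fft.ifft2(spectrum * transfer)
    return WaveField(out, field.pixel_size_m)


def fresnel_intensity(
    projection: PhantomProjection,
    geometry: PropagationGeometry,
    optics: OpticalConstants,
) -> np.ndarray:
    """Detected intensity |U_z|^2 of the propagated exit wave."""
    field = projection_to_wavefield(projection, geometry)
    return fresnel_propagate(field, geometry, optics).intensity


def periodic_laplacian(arr: np.ndarray, pixel_size_m: float) -> np.ndarray:
    """5-point finite-difference Laplacian with periodic boundaries, 1/m^2."""
    lap = (
        np.roll(arr, 1, axis=0)
        + np.roll(arr, -1, axis=0)
        + np.roll(arr, 1, axis=1)
        + np.roll(arr, -1, axis=1)
        - 4.0 * arr
    )
    return lap / pixel_size_m**2


def tie_intensity(
    projection: PhantomProjection,
    geometry: PropagationGeometry,
    optics: OpticalConstants,
) -> np.ndarray:
    """Linearized near-field intensity I = I0 * (1 - (lambda z / 2pi) lap(phi)).

    The Laplacian uses the 5-point periodic stencil so the implicit boundary
    model matches the Fourier propagator.  The linearization can undershoot
    zero at strong edges; negative values are clipped to 0 and the clip count
    logged.
    """
    lam = optics.wavelength
    z = geometry.distance_m
    lap = periodic_laplacian(projection.phase, geometry.pixel_size_m)
    intensity = projection.contact_intensity * (1.0 - lam * z / (2.0 * np.pi) * lap)
    n_neg = int(np.count_nonzero(intensity < 0))
    if n_neg:
        logger.info("tie_intensity: clipped %d negative pixels to 0", n_neg)
        intensity = np.clip(intensity, 0.0, None)
    return intensity
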