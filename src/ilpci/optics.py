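"""X-ray optical constants and propagation geometry.

A monochromatic plane wave of energy E traverses the sample; each material m
is described by the complex refractive index n = 1 - delta + i*beta, where
delta (the real decrement) sets the phase shift accumulated per unit
thickness and beta the absorption.  Default constants approximate soft
tissue at 15 keV (water-like electron density), with small density offsets
between parenchyma, viable tumor, necrotic material and blood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hc in m*keV: lambda[m] = HC_M_KEV / E[keV]
HC_M_KEV = 1.23984193e-9


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon energy in keV -> wavelength in meters (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_M_KEV / energy_kev


@dataclass(frozen=True)
class Material:
    """Refractive-index decrement and absorption index of one material."""

    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")


@dataclass(frozen=True)
class OpticalConstants:
    """Beam energy plus per-material (delta, beta) at that energy."""

    energy_kev: float
    materials: dict[str, Material] = field(default_factory=dict)

    @property
    def wavelength(self) -> float:
        return energy_to_wavelength(self.energy_kev)

    @property
    def wave_number(self) -> float:
        """k = 2*pi/lambda in 1/m."""
        return 2.0 * np.pi / self.wavelength

    def material(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise KeyError(
                f"no optical constants for material {name!r}; "
                f"known: {sorted(self.materials)}"
            ) from None


def soft_tissue_materials() -> dict[str, Material]:
    """Nominal (delta, beta) at 15 keV.

    delta for water at 15 keV is ~1.0e-6 (from delta = r_e lambda^2 n_e / 2pi
    with n_e ~ 3.34e29 m^-3); beta ~ 1.1e-9 (from mu ~ 1.7 cm^-1,
    beta = mu lambda / 4pi).  Tissue variants are small density offsets.
    """
    return {
        "parenchyma": Material(delta=1.00e-6, beta=1.10e-9),
        "tumor": Material(delta=1.05e-6, beta=1.16e-9),
        "necrosis": Material(delta=1.12e-6, beta=1.25e-9),
        "vessel": Material(delta=1.03e-6, beta=1.13e-9),
    }


def default_optics(energy_kev: float = 15.0) -> OpticalConstants:
    return OpticalConstants(energy_kev=energy_kev, materials=soft_tissue_materials())


@dataclass(frozen=True)
class PropagationGeometry:
    """Free-space propagation geometry (plane-wave illumination).

    distance_m: sample-to-detector distance z in meters.
    pixel_size_m: detector pixel pitch in meters.
    grid_shape: (rows, cols); both must be even for the Fourier and
        half-band wavelet grids used downstream.
    """

    distance_m: float
    pixel_size_m: float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError("propagation distance must be >= 0")
        if not self.pixel_size_m > 0:
            raise ValueError("pixel size must be positive")
        rows, cols = self.grid_shape
        if rows % 2 or cols % 2 or rows <= 0 or cols <= 0:
            raise ValueError(f"grid dimensions must be positive and even, got {self.grid_shape}")

    def frequency_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial-frequency grids (u, v) in cycles/meter, FFT layout."""
        rows, cols = self.grid_shape
        v = np.fft.fftfreq(rows, d=self.pixel_size_m)
        u = np.fft.fftfreq(cols, d=self.pixel_size_m)
        return u[np.newaxis, :], v[:, np.newaxis]


def default_geometry(grid_shape: tuple[int, int] = (1024, 1024)) -> PropagationGeometry:
    """15 keV beamline defaults: z = 0.5 m, 9 um detector pixels."""
    return PropagationGeometry(distance_m=0.5, pixel_size_m=9e-6, grid_shape=grid_shape)
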