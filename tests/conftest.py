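import numpy as np
import pytest

from ilpci.optics import OpticalConstants, Material, PropagationGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def beam_15kev():
    """15 keV beam with a single water-like material."""
    return OpticalConstants(
        energy_kev=15.0,
        materials={"water": Material(delta=1.0e-6, beta=1.1e-9)},
    )


@pytest.fixture
def geometry_512():
    """Default acquisition geometry on a 512x512 grid: z=0.5 m, 9 um pixels."""
    return PropagationGeometry(distance_m=0.5, pixel_size_m=9e-6, grid_shape=(512, 512))


def gaussian_phase_projection(phi0, sigma_px=40.0, shape=(512, 512)):
    """Pure-phase Gaussian bump phi = phi0 * exp(-r^2 / 2 sigma^2)."""
    from ilpci.projection import PhantomProjection

    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    r2 = (rr - rows // 2) ** 2 + (cc - cols // 2) ** 2
    phase = phi0 * np.exp(-r2 / (2.0 * sigma_px**2))
    return PhantomProjection(phase=phase, contact_intensity=np.ones(shape))
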