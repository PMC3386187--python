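"""Wave-optics forward model: projection, Fresnel propagation, TIE limit."""

import numpy as np
import pytest

from ilpci.optics import PropagationGeometry, energy_to_wavelength
from ilpci.projection import (
    PhantomProjection,
    fresnel_intensity,
    fresnel_propagate,
    max_alias_free_distance,
    periodic_laplacian,
    project_scene,
    projection_to_wavefield,
    tie_intensity,
)

from .conftest import gaussian_phase_projection


class TestEnergyWavelength:
    def test_15_kev(self):
        assert energy_to_wavelength(15.0) == pytest.approx(8.2656e-11, rel=1e-4)

    def test_one_angstrom_energy(self):
        assert energy_to_wavelength(12.398) == pytest.approx(1.00005e-10, rel=1e-4)

    @pytest.mark.parametrize("e1,e2", [(8.0, 30.0), (15.0, 72.5)])
    def test_inverse_proportionality(self, e1, e2):
        assert e1 * energy_to_wavelength(e1) == pytest.approx(e2 * energy_to_wavelength(e2), rel=1e-14)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_to_wavelength(0.0)


class TestGeometry:
    def test_wave_number_consistency(self, beam_15kev):
        assert beam_15kev.wave_number * beam_15kev.wavelength == pytest.approx(2 * np.pi, rel=1e-12)

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError):
            PropagationGeometry(0.5, 9e-6, (511, 512))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            PropagationGeometry(-0.1, 9e-6, (64, 64))


class TestProjectScene:
    def test_empty_object(self, beam_15kev):
        proj = project_scene({"water": np.zeros((32, 32))}, beam_15kev)
        assert np.all(proj.phase == 0)
        assert np.all(proj.contact_intensity == 1.0)

    def test_uniform_slab_closed_form(self, beam_15kev):
        t = 2.0e-3
        proj = project_scene({"water": np.full((16, 16), t)}, beam_15kev)
        k = beam_15kev.wave_number
        m = beam_15kev.material("water")
        assert proj.phase == pytest.approx(-k * m.delta * t, rel=1e-12)
        assert proj.contact_intensity == pytest.approx(np.exp(-2 * k * m.beta * t), rel=1e-12)

    def test_thickness_doubling(self, beam_15kev, rng):
        t = 1e-4 * rng.random((16, 16))
        p1 = project_scene({"water": t}, beam_15kev)
        p2 = project_scene({"water": 2 * t}, beam_15kev)
        np.testing.assert_allclose(p2.phase, 2 * p1.phase, rtol=1e-12)
        np.testing.assert_allclose(p2.contact_intensity, p1.contact_intensity**2, rtol=1e-12)

    def test_missing_material_raises(self, beam_15kev):
        with pytest.raises(KeyError, match="marrow"):
            project_scene({"marrow": np.ones((8, 8))}, beam_15kev)


class TestFresnelPropagate:
    def test_zero_distance_identity(self, beam_15kev, rng):
        geom = PropagationGeometry(0.0, 9e-6, (64, 64))
        proj = PhantomProjection(
            phase=rng.standard_normal((64, 64)) * 0.1,
            contact_intensity=np.ones((64, 64)),
        )
        field = projection_to_wavefield(proj, geom)
        out = fresnel_propagate(field, geom, beam_15kev)
        np.testing.assert_allclose(out.complex_amplitude, field.complex_amplitude, atol=1e-12)

    @pytest.mark.parametrize("z", [0.1, 0.5, 1.0])
    def test_pure_phase_intensity_conserved(self, beam_15kev, z, rng):
        geom = PropagationGeometry(z, 9e-6, (128, 128))
        phase = 0.3 * np.cos(np.linspace(0, 6 * np.pi, 128))[None, :] * np.ones((128, 1))
        phase += 0.1 * rng.standard_normal((128, 128))
        proj = PhantomProjection(phase=phase, contact_intensity=np.ones((128, 128)))
        field = projection_to_wavefield(proj, geom)
        out = fresnel_propagate(field, geom, beam_15kev)
        assert out.intensity.sum() == pytest.approx(field.intensity.sum(), rel=1e-9)

    def test_weak_gaussian_bump_matches_tie_closed_form(self, beam_15kev, geometry_512):
        phi0, sigma_px = 0.05, 40.0
        proj = gaussian_phase_projection(phi0, sigma_px)
        intensity = fresnel_intensity(proj, geometry_512, beam_15kev)
        center = intensity[256, 256]
        sigma_m = sigma_px * geometry_512.pixel_size_m
        lam = beam_15kev.wavelength
        expected = 1.0 + lam * geometry_512.distance_m / np.pi * phi0 / sigma_m**2
        # compare the phase-contrast deviation from unity, not the raw intensity
        assert (center - 1.0) == pytest.approx(expected - 1.0, rel=0.01)

    def test_aliasing_guard_warns(self, beam_15kev):
        geom = PropagationGeometry(5.0, 9e-6, (64, 64))
        field = projection_to_wavefield(
            PhantomProjection(np.zeros((64, 64)), np.ones((64, 64))), geom
        )
        assert max_alias_free_distance(geom, beam_15kev) < 5.0
        with pytest.warns(RuntimeWarning, match="alias"):
            fresnel_propagate(field, geom, beam_15kev)

    def test_shape_mismatch_raises(self, beam_15kev, geometry_512):
        field = projection_to_wavefield(
            PhantomProjection(np.zeros((64, 64)), np.ones((64, 64))),
            PropagationGeometry(0.5, 9e-6, (64, 64)),
        )
        with pytest.raises(ValueError):
            fresnel_propagate(field, geometry_512, beam_15kev)


class TestTieIntensity:
    def test_linear_ramp_is_contact_image(self, beam_15kev):
        rows, cols = 64, 64
        rr, cc = np.mgrid[0:rows, 0:cols]
        # periodic stencil: use a ramp constant along the wrap direction
        phase = 0.01 * np.ones((rows, cols)) * np.sin(0)  # zero field
        phase = np.zeros((rows, cols)) + 0.3
        i0 = np.full((rows, cols), 0.9)
        geom = PropagationGeometry(0.5, 9e-6, (rows, cols))
        out = tie_intensity(PhantomProjection(phase, i0), geom, beam_15kev)
        np.testing.assert_allclose(out, i0, rtol=1e-12)

    def test_gaussian_bump_center(self, beam_15kev, geometry_512):
        phi0, sigma_px = 0.05, 40.0
        proj = gaussian_phase_projection(phi0, sigma_px)
        out = tie_intensity(proj, geometry_512, beam_15kev)
        sigma_m = sigma_px * geometry_512.pixel_size_m
        lam = beam_15kev.wavelength
        expected = 1.0 + lam * geometry_512.distance_m / np.pi * phi0 / sigma_m**2
        assert (out[256, 256] - 1.0) == pytest.approx(expected - 1.0, rel=0.01)

    def test_periodic_laplacian_of_plane_wave(self):
        x = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        f = np.sin(4 * x)[None, :] * np.ones((64, 1))
        lap = periodic_laplacian(f, 1.0)
        # discrete eigenvalue of the 5-point stencil: 2(cos(w)-1)
        w = 4 * (2 * np.pi / 64)
        np.testing.assert_allclose(lap, 2 * (np.cos(w) - 1) * f, atol=1e-10)

    def test_agrees_with_fresnel_in_weak_limit(self, beam_15kev, geometry_512):
        proj = gaussian_phase_projection(0.05)
        i_f = fresnel_intensity(proj, geometry_512, beam_15kev)
        i_t = tie_intensity(proj, geometry_512, beam_15kev)
        rms = np.sqrt(np.mean(((i_f - i_t) / i_t) ** 2))
        assert rms < 0.02

    def test_fresnel_tie_difference_shrinks_with_phase(self, beam_15kev, geometry_512):
        rms = []
        for phi0 in (0.2, 0.1, 0.05, 0.025):
            proj = gaussian_phase_projection(phi0)
            i_f = fresnel_intensity(proj, geometry_512, beam_15kev)
            i_t = tie_intensity(proj, geometry_512, beam_15kev)
            rms.append(float(np.sqrt(np.mean(((i_f - i_t) / i_t) ** 2))))
        assert all(a > b for a, b in zip(rms, rms[1:]))


class TestEdgeEnhancement:
    def test_step_overshoot_at_distance(self, beam_15kev):
        """A material step shows an overshoot/undershoot fringe pair after
        propagation that the contact image lacks."""
        shape = (256, 256)
        step = np.zeros(shape)
        step[:, 128:] = 1.0
        t = 2.0e-4 * step
        proj = project_scene({"water": t}, beam_15kev)
        contact = proj.contact_intensity
        geom = PropagationGeometry(0.5, 9e-6, shape)
        propagated = fresnel_intensity(proj, geom, beam_15kev)
        row = shape[0] // 2
        contrast_contact = contact[row].max() - contact[row].min()
        contrast_fresnel = propagated[row].max() - propagated[row].min()
        assert contrast_fresnel > contrast_contact
        # fringe: intensity exceeds both plateau values near the edge
        assert propagated[row].max() > contact[row].max()
        assert propagated[row].min() < contact[row].min()
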