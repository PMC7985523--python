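"""Optical forward models: layered closed forms, Monte Carlo oracles."""

import numpy as np
import pytest

from lsdpa import (MCConfig, PhantomSpec, fluence_layered, fluence_mc,
                   initial_pressure, sample_phantom, simulate_multispectral)
from lsdpa.errors import ValidationError
from lsdpa.fluence import FluenceMap


def _homog(shape, mu_a, mu_sp):
    return np.full(shape, mu_a), np.full(shape, mu_sp)


class TestLayered:
    def test_beer_lambert_closed_form(self):
        """mu_a = 1/cm, no scattering: phi(z) = exp(-z), 0.3679 at 1 cm."""
        mu_a, mu_sp = _homog((4, 200), 1.0, 0.0)
        phi = fluence_layered(mu_a, mu_sp, voxel_size_mm=0.1)
        z_cm = (np.arange(200) + 0.5) * 0.01
        np.testing.assert_allclose(phi.values[0], np.exp(-z_cm), rtol=1e-12)
        at_1cm = np.interp(1.0, z_cm, phi.values[0])
        assert at_1cm == pytest.approx(np.exp(-1.0), rel=1e-4)

    def test_no_absorption_no_decay(self):
        mu_a, mu_sp = _homog((3, 50), 0.0, 0.0)
        phi = fluence_layered(mu_a, mu_sp, 0.1)
        np.testing.assert_array_equal(phi.values, 1.0)

    def test_diffusion_decay_constant(self):
        """mu_a=0.1, mu_s'=10: mu_eff = sqrt(3*0.1*10.1) ~ 1.7407 /cm."""
        mu_a, mu_sp = _homog((2, 300), 0.1, 10.0)
        phi = fluence_layered(mu_a, mu_sp, 0.1)
        logphi = np.log(phi.values[0])
        slopes = -np.diff(logphi) / 0.01
        np.testing.assert_allclose(slopes, np.sqrt(3 * 0.1 * 10.1),
                                   rtol=1e-10)
        assert np.sqrt(3 * 0.1 * 10.1) == pytest.approx(1.7407, abs=1e-4)

    def test_monotone_decrease_with_depth(self):
        mu_a, mu_sp = _homog((5, 80), 0.3, 8.0)
        phi = fluence_layered(mu_a, mu_sp, 0.1)
        assert np.all(np.diff(phi.values, axis=-1) <= 0)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValidationError):
            fluence_layered(np.full((2, 4), -1.0), np.zeros((2, 4)), 0.1)


class TestMonteCarlo:
    def test_nonscattering_slab_matches_beer_lambert(self):
        """Pencil beam, no scattering: depth profile equals the analytic
        voxel-averaged Beer-Lambert solution (continuous absorption makes
        the straight-line path deterministic)."""
        shape = (5, 5, 20)
        mu_a = np.full(shape, 1.0)
        zeros = np.zeros(shape)
        f = fluence_mc(mu_a, zeros, zeros, voxel_size_mm=0.5,
                       illumination="pencil",
                       cfg=MCConfig(photon_count=5000, seed=1))
        dz = 0.05  # cm
        z = (np.arange(20) + 0.5) * dz
        voxel_avg = np.exp(-z) * np.sinh(dz / 2) / (dz / 2)
        np.testing.assert_allclose(f.values[2, 2, :], voxel_avg, rtol=1e-9)

    def test_pure_scatterer_deposits_no_energy(self):
        shape = (10, 10, 10)
        zeros = np.zeros(shape)
        f = fluence_mc(zeros, np.full(shape, 5.0), zeros, 1.0, "pencil",
                       MCConfig(photon_count=2000, seed=2))
        assert f.energy_ledger["absorbed"] == 0.0
        assert np.all(np.isfinite(f.values)) and np.all(f.values >= 0)
        assert f.values.max() > 0

    def test_energy_ledger_closes(self):
        shape = (12, 12, 16)
        f = fluence_mc(np.full(shape, 0.5), np.full(shape, 10.0),
                       np.full(shape, 0.8), 1.0, "slab",
                       MCConfig(photon_count=5000, seed=3))
        led = f.energy_ledger
        total = (led["absorbed"] + led["escaped"] + led["roulette_net"]
                 + led["residual"])
        assert abs(total - led["injected"]) / led["injected"] < 1e-6

    def test_seeded_runs_bit_reproducible(self):
        shape = (8, 8, 12)
        args = (np.full(shape, 0.2), np.full(shape, 3.0),
                np.full(shape, 0.5), 1.0, "slab")
        f1 = fluence_mc(*args, MCConfig(photon_count=3000, seed=9))
        f2 = fluence_mc(*args, MCConfig(photon_count=3000, seed=9))
        assert np.array_equal(f1.values, f2.values)

    def test_diffusive_decay_matches_mu_eff(self):
        """Asymptotic log-slope in a scattering slab within 10% of
        sqrt(3*mu_a*(mu_a+mu_s'))."""
        shape = (40, 40, 50)
        mu_a_v, mu_s_v = 0.5, 10.0
        f = fluence_mc(np.full(shape, mu_a_v), np.full(shape, mu_s_v),
                       np.zeros(shape), 1.0, "slab",
                       MCConfig(photon_count=40_000, seed=5))
        prof = f.values[15:25, 15:25, :].mean(axis=(0, 1))
        z = (np.arange(50) + 0.5) * 0.1
        lo, hi = 8, 18  # beyond 3 transport mean free paths
        slope = -np.polyfit(z[lo:hi], np.log(prof[lo:hi]), 1)[0]
        mu_eff = np.sqrt(3 * mu_a_v * (mu_a_v + mu_s_v))
        assert slope == pytest.approx(mu_eff, rel=0.10)

    def test_invalid_anisotropy_rejected(self):
        shape = (4, 4, 4)
        with pytest.raises(ValidationError):
            fluence_mc(np.zeros(shape), np.ones(shape), np.ones(shape),
                       1.0, "pencil", MCConfig(photon_count=10, seed=0))


class TestInitialPressure:
    def test_zero_absorption_zero_pressure(self):
        phi = FluenceMap(np.ones((4, 6)), 800.0, "slab", 0.1)
        mu_a = np.zeros((4, 6))
        mu_a[1, 2] = 2.0
        p0 = initial_pressure(mu_a, phi)
        assert p0.values[0, 0] == 0.0
        assert p0.values[1, 2] == 2.0

    def test_linear_in_gruneisen(self):
        phi = FluenceMap(np.full((3, 3), 0.5), 800.0, "slab", 0.1)
        mu_a = np.full((3, 3), 1.2)
        np.testing.assert_allclose(
            initial_pressure(mu_a, phi, gruneisen=2.0).values,
            2 * initial_pressure(mu_a, phi, gruneisen=1.0).values)

    def test_shape_mismatch_rejected(self):
        phi = FluenceMap(np.ones((3, 3)), 800.0, "slab", 0.1)
        with pytest.raises(ValidationError):
            initial_pressure(np.ones((4, 3)), phi)


class TestMultispectral:
    def test_generic_grid_yields_26_maps(self, table):
        spec = PhantomSpec("generic", grid_shape=(48, 48), voxel_size_mm=0.2)
        vol = sample_phantom(spec, np.random.default_rng(0))
        wl = np.arange(700, 951, 10)
        stack = simulate_multispectral(vol, wl, table)
        assert stack.values.shape == (26, 48, 48)

    def test_flow_grid_yields_17_maps(self, table):
        from lsdpa import FLOW_WAVELENGTHS
        spec = PhantomSpec("flow", grid_shape=(48, 96), voxel_size_mm=0.15)
        vol = sample_phantom(spec, np.random.default_rng(1))
        stack = simulate_multispectral(vol, np.array(FLOW_WAVELENGTHS), table)
        assert stack.values.shape[0] == 17

    def test_mc_model_deterministic_given_seed(self, table):
        spec = PhantomSpec("generic", grid_shape=(24, 24), voxel_size_mm=0.3)
        vol = sample_phantom(spec, np.random.default_rng(2))
        wl = np.array([750.0, 850.0])
        cfg = MCConfig(photon_count=2000, seed=7)
        s1 = simulate_multispectral(vol, wl, table, model="mc", mc_config=cfg)
        s2 = simulate_multispectral(vol, wl, table, model="mc", mc_config=cfg)
        assert np.array_equal(s1.values, s2.values)


def test_spectral_coloring_grows_with_depth(table):
    """A vessel under an absorbing background shows a depth-dependent
    normalized spectrum: the shallow and deep spectra differ in l1 norm.
    This is the phenomenon the learned regressor corrects."""
    from lsdpa.chromophores import TissueComposition
    from lsdpa.phantoms import LabeledVolume
    from lsdpa.spectra import normalize_spectrum

    wl = np.arange(700, 951, 10.0)
    labels = np.zeros((4, 120), dtype=int)
    labels[:, 40] = 1   # shallow vessel sheet at 4 mm
    labels[:, 100] = 2  # deep vessel sheet at 10 mm
    bg = TissueComposition(blood_volume_fraction=0.05, oxygenation=0.6,
                           mus_prime_ref=10.0)
    blood = TissueComposition(blood_volume_fraction=1.0, oxygenation=0.6,
                              mus_prime_ref=10.0)
    vol = LabeledVolume(labels, {0: bg, 1: blood, 2: blood},
                        {0: 0.6, 1: 0.6, 2: 0.6}, {0: "bg", 1: "v", 2: "v"},
                        {1, 2}, "slab", 0.1)
    stack = simulate_multispectral(vol, wl, table)
    shallow = normalize_spectrum(stack.values[:, 0, 40], wl).values
    deep = normalize_spectrum(stack.values[:, 0, 100], wl).values
    assert np.abs(shallow - deep).sum() > 1e-3
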