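"""Transport-engine invariants: conservation, determinism, symmetry, limits.

Photon counts here are kept moderate; the heavier statistically-binding
validations (diffusion-theory agreement, full conservation battery) live
in the acceptance suite.
"""

import numpy as np
import pytest

from ewdrs.mc_engine import (
    DetectionResult,
    PhotonState,
    ProbeGeometry,
    TransportSettings,
    diffusion_reflectance_oracle,
    simulate_detected_reflectance,
    simulate_spectrum,
    trace_photon,
)
from ewdrs.optical_props import OpticalProperties
from ewdrs.tissue_models import build_homogeneous, build_plexus, build_two_layer

PROBE = ProbeGeometry()


def homog(mu_a, mu_sp, g=0.9, n=1.34):
    return build_homogeneous(OpticalProperties.constant(mu_a, mu_sp, g=g, n=n))


class TestProbeGeometry:
    def test_hexagonal_detector_ring(self):
        c = PROBE.detector_centers
        assert c.shape == (6, 2)
        radii = np.hypot(c[:, 0], c[:, 1])
        assert np.allclose(radii, 0.66)

    def test_overlap_guard(self):
        with pytest.raises(ValueError):
            ProbeGeometry(core_radius_mm=0.4, center_spacing_mm=0.66)

    def test_na_bounds(self):
        with pytest.raises(ValueError):
            ProbeGeometry(numerical_aperture=1.2)


class TestPhotonState:
    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError):
            PhotonState(np.zeros(3), np.array([0.0, 0.0, 2.0]))

    def test_weight_in_unit_interval(self):
        with pytest.raises(ValueError):
            PhotonState(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=1.5)


class TestConservation:
    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_ledger_balances(self, seed):
        rng = np.random.default_rng(seed)
        model = homog(rng.uniform(0.01, 1.0), rng.uniform(0.5, 3.0))
        r = simulate_detected_reflectance(model, PROBE, 800.0, 5000, seed=seed)
        assert r.ledger_total == pytest.approx(1.0, abs=1e-6)
        assert r.detected_total <= r.diffuse_reflectance + 1e-12

    def test_opaque_medium_fully_absorbed(self):
        model = homog(1e3, 1.0, n=1.0)
        r = simulate_detected_reflectance(model, PROBE, 800.0, 20_000, seed=2)
        assert r.absorbed == pytest.approx(1.0, abs=1e-3)

    def test_nonabsorbing_matched_medium_total_reflectance_unity(self):
        model = homog(0.0, 1.0, n=1.0)
        r = simulate_detected_reflectance(model, PROBE, 800.0, 20_000, seed=3)
        assert r.specular == 0.0
        assert r.diffuse_reflectance == pytest.approx(1.0, abs=1e-3)


class TestDeterminism:
    def test_identical_arguments_bitwise_identical(self):
        model = homog(0.05, 1.5)
        a = simulate_detected_reflectance(model, PROBE, 900.0, 4000, seed=11)
        b = simulate_detected_reflectance(model, PROBE, 900.0, 4000, seed=11)
        assert np.array_equal(a.detector_fractions, b.detector_fractions)
        assert a.absorbed == b.absorbed

    def test_seed_changes_result(self):
        model = homog(0.05, 1.5)
        a = simulate_detected_reflectance(model, PROBE, 900.0, 4000, seed=11)
        b = simulate_detected_reflectance(model, PROBE, 900.0, 4000, seed=12)
        assert not np.array_equal(a.detector_fractions, b.detector_fractions)

    def test_two_layer_with_identical_materials_equals_homogeneous(self):
        mat = OpticalProperties.constant(0.05, 1.5)
        h = simulate_spectrum(build_homogeneous(mat), PROBE, [600.0, 1200.0], 5000, seed=9)
        t = simulate_spectrum(
            build_two_layer(mat, 2.0, mat, 40.0), PROBE, [600.0, 1200.0], 5000, seed=9
        )
        assert np.array_equal(h.spectrum.values, t.spectrum.values)


class TestDetectorSymmetry:
    def test_hexagonal_fractions_agree_within_3_sigma(self):
        model = homog(0.05, 1.5)
        r = simulate_detected_reflectance(model, PROBE, 800.0, 60_000, seed=17)
        f = r.detector_fractions
        se = r.detector_stderr()
        mean = f.mean()
        pooled = np.sqrt(se**2 + (se**2).mean())
        assert np.all(np.abs(f - mean) < 3.0 * pooled)


class TestTracePhoton:
    def test_terminal_event_classification(self):
        events = set()
        model = homog(0.5, 1.5)
        for seed in range(60):
            ev, rec = trace_photon(model, PROBE, 800.0, seed=seed)
            events.add(ev.split(":")[0])
            assert rec.ledger_total == pytest.approx(1.0, abs=1e-6)
        # overwhelmingly roulette-absorbed or escaped at these properties
        assert events & {"escaped", "roulette", "detector"}


class TestSpectrumSweep:
    def test_constant_properties_give_flat_spectrum(self):
        model = homog(0.1, 1.5)
        sim = simulate_spectrum(model, PROBE, [600.0, 900.0, 1300.0], 30_000, seed=21)
        vals = sim.spectrum.values
        se = np.array([np.sqrt(np.sum(r.detector_sq)) for r in sim.results])
        spread = np.abs(vals - vals.mean())
        assert np.all(spread < 4.0 * np.sqrt(se**2 + (se**2).mean()))

    def test_per_detector_spectra_sum_to_total(self):
        model = homog(0.1, 1.5)
        sim = simulate_spectrum(model, PROBE, [700.0, 1100.0], 3000, seed=4)
        assert np.allclose(sim.per_detector.sum(axis=0), sim.spectrum.values)

    def test_wavelength_outside_property_grid_rejected(self):
        mat = OpticalProperties.constant(0.1, 1.0, grid=np.array([600.0, 900.0]))
        with pytest.raises(ValueError):
            simulate_spectrum(build_homogeneous(mat), PROBE, [500.0], 100, seed=0)


class TestVoxelTransport:
    def test_voxel_ledger_and_determinism(self):
        nerve = OpticalProperties.constant(0.1, 1.5, name="nerve")
        muscle = OpticalProperties.constant(0.3, 1.2, name="muscle")
        vm = build_plexus(0.5, nerve, muscle, voxel_mm=0.2)
        a = simulate_detected_reflectance(vm, PROBE, 800.0, 3000, seed=5)
        b = simulate_detected_reflectance(vm, PROBE, 800.0, 3000, seed=5)
        assert a.ledger_total == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(a.detector_fractions, b.detector_fractions)

    def test_mixed_refractive_index_rejected(self):
        a = OpticalProperties.constant(0.1, 1.5, n=1.34)
        b = OpticalProperties.constant(0.3, 1.2, n=1.40)
        vm = build_plexus(0.5, a, b, voxel_mm=0.2)
        with pytest.raises(ValueError):
            simulate_detected_reflectance(vm, PROBE, 800.0, 100, seed=0)


class TestDiffusionOracle:
    def test_monotone_decrease_in_rho(self):
        rho = np.linspace(1.0, 5.0, 41)
        R = diffusion_reflectance_oracle(0.01, 1.0, 1.34, rho)
        assert np.all(np.diff(R) < 0)

    def test_absorption_monotonicity(self):
        rho = np.linspace(1.0, 4.0, 13)
        low = diffusion_reflectance_oracle(0.01, 1.0, 1.34, rho)
        high = diffusion_reflectance_oracle(0.02, 1.0, 1.34, rho)
        assert np.all(high < low)

    def test_warns_outside_diffusive_regime(self):
        with pytest.warns(UserWarning):
            diffusion_reflectance_oracle(0.5, 1.0, 1.34, 2.0)
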