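"""Synthetic study generator: presets, triplet round trips, datasets.

Monte Carlo settings are kept tiny here (coarse grids, few thousand
photons); these tests check construction contracts and qualitative
features, not transport statistics.
"""

import numpy as np
import pytest

from ewdrs.analysis import peak_ratio
from ewdrs.spectra import Spectrum, reference_spectrum
from ewdrs.synthdata import (
    PRESETS,
    NoiseModel,
    PhantomRecipe,
    TISSUE_CLASS_COUNTS,
    make_labeled_dataset,
    make_measurement_triplet,
    make_properties,
    make_repeats,
    phantom_study,
)

TINY_MC = {"grid": np.array([550.0, 800.0, 1000.0, 1210.0, 1270.0, 1450.0]), "n_photons": 1500, "swir_factor": 1}


class TestPresets:
    def test_nm_phantom_lipid_features(self):
        p = make_properties("nm_phantom")
        w = p.wavelengths_nm
        win = (w >= 1150) & (w <= 1300)
        assert w[win][np.argmax(p.mu_a[win])] == 1210.0

    def test_nm_phantom_has_no_blood_pigment(self):
        assert PRESETS["nm_phantom"].chromophores["blood"] == 0.0
        assert PRESETS["nm_phantom"].chromophores["heme_dye"] == 0.0

    def test_mm_phantom_heme_band_and_low_lipid(self):
        p = make_properties("mm_phantom")
        w = p.wavelengths_nm
        win = (w >= 550) & (w <= 700)
        assert abs(w[win][np.argmax(p.mu_a[win])] - 630.0) <= 2.0
        assert (
            PRESETS["mm_phantom"].chromophores["lipid"]
            < PRESETS["nm_phantom"].chromophores["lipid"]
        )

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_scattering_strictly_decreasing(self, name):
        p = make_properties(name)
        assert np.all(np.diff(p.mu_s_prime) < 0)

    def test_nm_phantom_shoulder_curvature_near_1180(self):
        # the 1180-nm lipid shoulder appears as a distinct concavity
        # minimum in mu_a beside the 1210-nm main band
        p = make_properties("nm_phantom")
        w, m = p.wavelengths_nm, p.mu_a
        d2 = np.diff(m, n=2)
        wd2 = w[1:-1]
        sel = (wd2 >= 1165) & (wd2 <= 1195)
        most_concave = wd2[sel][np.argmin(d2[sel])]
        assert 1175 <= most_concave <= 1185
        assert d2[sel].min() < 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            make_properties("granite")

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            PhantomRecipe("x", {"lipid": -1.0}, (1.0, 500.0, 0.1))


class TestMeasurementTriplets:
    def _truth(self):
        grid = np.arange(500.0, 1000.5, 5.0)
        return Spectrum(grid, 0.5 + 0.3 * np.sin(grid / 80.0) ** 2, "visnir")

    def test_zero_noise_roundtrip_exact(self):
        truth = self._truth()
        trip = make_measurement_triplet(truth, NoiseModel(0.0, 0.0), 0)
        back = reference_spectrum(trip)
        assert np.allclose(back.values, truth.values, rtol=0, atol=1e-12)

    def test_repeat_sd_tracks_gain_jitter(self):
        truth = self._truth()
        noise = NoiseModel(gain_sd=0.02, additive_sd_frac=0.0, seed=3)
        refs = [
            reference_spectrum(make_measurement_triplet(truth, noise, k)).values
            for k in range(12)
        ]
        stack = np.stack(refs)
        rel_sd = stack.std(axis=0, ddof=1) / stack.mean(axis=0)
        assert np.all(rel_sd > 0.01) and np.all(rel_sd < 0.04)

    def test_repeat_substream_contract(self):
        truth = self._truth()
        noise = NoiseModel(gain_sd=0.02, additive_sd_frac=0.005, seed=5)
        t0 = make_measurement_triplet(truth, noise, 0)
        t1 = make_measurement_triplet(truth, noise, 1)
        t0b = make_measurement_triplet(truth, noise, 0)
        assert not np.array_equal(t0.m_raw.values, t1.m_raw.values)
        assert np.array_equal(t0.m_raw.values, t0b.m_raw.values)
        assert np.array_equal(t0.m_std.values, t1.m_std.values)


class TestLabeledDatasets:
    def test_counting_contract(self):
        data = make_labeled_dataset(
            ["nerve", "muscle"], n_per_class=3, mc_settings=TINY_MC, seed=1
        )
        assert data.X.shape[0] == 6
        assert sorted(set(data.labels)) == ["muscle", "nerve"]

    def test_repeats_use_independent_photon_streams(self):
        # repeats within a class differ by MC counting variance even with
        # zero instrument noise, but regeneration is fully deterministic
        kwargs = dict(
            classes=["nerve", "muscle"],
            n_per_class=3,
            mc_settings=TINY_MC,
            noise=NoiseModel(0.0, 0.0),
            seed=1,
        )
        data = make_labeled_dataset(**kwargs)
        nerve_rows = data.X[data.labels == "nerve"]
        assert not np.array_equal(nerve_rows[0], nerve_rows[1])
        again = make_labeled_dataset(**kwargs)
        assert np.array_equal(data.X, again.X)

    def test_nerve_lower_swir_ratio_than_muscle(self):
        data = make_labeled_dataset(
            ["nerve", "muscle"],
            n_per_class=2,
            mc_settings={"grid": np.array([1000.0, 1210.0, 1270.0]), "n_photons": 20_000, "swir_factor": 1},
            noise=NoiseModel(0.0, 0.0),
            seed=2,
            auc=False,
        )
        def ratio(row):
            s = Spectrum(data.wavelengths_nm, row, "merged")
            return peak_ratio(s, 1210.0, 1270.0)

        nerve = np.mean([ratio(r) for r in data.X[data.labels == "nerve"]])
        muscle = np.mean([ratio(r) for r in data.X[data.labels == "muscle"]])
        assert nerve < muscle

    def test_tissue_class_counts_match_study_margins(self):
        counts = TISSUE_CLASS_COUNTS
        assert sum(counts.values()) == 85
        assert counts["nerve"] + counts["nvb"] == 25
        assert sum(v for k, v in counts.items() if k not in ("nerve", "nvb")) == 60


class TestSimulatedPhantomFeatures:
    def test_reflectance_dips_at_the_designed_feature_wavelengths(self):
        """Simulated phantom spectra carry the designed spectral dips.

        The nerve-mimicking phantom shows its lipid reflectance minimum
        near 1210 nm and the muscle-mimicking phantom its heme-dye
        minimum near 630 nm.
        """
        from ewdrs.mc_engine import ProbeGeometry, simulate_spectrum
        from ewdrs.tissue_models import build_homogeneous

        probe = ProbeGeometry()
        nm_grid = np.arange(1150.0, 1301.0, 10.0)
        sim = simulate_spectrum(
            build_homogeneous(make_properties("nm_phantom")), probe, nm_grid, 20_000, seed=31
        )
        dip_nm = nm_grid[np.argmin(sim.spectrum.values)]
        assert 1190 <= dip_nm <= 1230, dip_nm

        mm_grid = np.arange(560.0, 701.0, 10.0)
        sim = simulate_spectrum(
            build_homogeneous(make_properties("mm_phantom")), probe, mm_grid, 20_000, seed=32
        )
        dip_mm = mm_grid[np.argmin(sim.spectrum.values)]
        assert 610 <= dip_mm <= 650, dip_mm


class TestPhantomStudy:
    def test_five_phantoms_five_repeats(self):
        study = phantom_study(mc_settings=TINY_MC, n_repeats=5, seed=3)
        assert len(study) == 5
        total = sum(len(v["repeats"]) for v in study.values())
        assert total == 25
        assert {"nm_homogeneous", "mm_homogeneous"} <= set(study)
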