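"""Dual-band preprocessing chain: referencing, smoothing, band merging."""

import numpy as np
import pytest

from ewdrs.spectra import (
    DegenerateMatchError,
    GridMismatchError,
    InvalidReferenceError,
    MatchResult,
    ReferenceTriplet,
    Spectrum,
    SpectrumError,
    matching_factor,
    merge_bands,
    read_spectrum_csv,
    reference_spectrum,
    resample,
    savitzky_golay,
    write_spectrum_csv,
)

VIS_GRID = np.arange(500.0, 1000.5, 2.0)
SWIR_GRID = np.arange(1000.0, 1500.5, 2.0)


def vis(values):
    return Spectrum(VIS_GRID, np.broadcast_to(values, VIS_GRID.shape).copy(), "visnir")


def swir(values):
    return Spectrum(SWIR_GRID, np.broadcast_to(values, SWIR_GRID.shape).copy(), "swir")


class TestSpectrumConstruction:
    def test_rejects_descending_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum([600.0, 550.0], [1.0, 1.0], "visnir")

    def test_rejects_nonfinite_values(self):
        with pytest.raises(SpectrumError):
            Spectrum([600.0, 650.0], [1.0, np.nan], "visnir")

    @pytest.mark.parametrize(
        "band,grid",
        [("visnir", [400.0, 900.0]), ("swir", [900.0, 1200.0]), ("merged", [500.0, 1600.0])],
    )
    def test_band_range_enforced(self, band, grid):
        with pytest.raises(SpectrumError):
            Spectrum(grid, [1.0, 1.0], band)

    def test_length_mismatch(self):
        with pytest.raises(SpectrumError):
            Spectrum([600.0, 650.0], [1.0], "visnir")


class TestReferencing:
    def test_identity_case(self):
        # Mraw == Mstd, zero background -> flat unity reflectance
        t = ReferenceTriplet(m_raw=vis(0.9), bg=vis(0.0), m_std=vis(0.9))
        assert np.allclose(reference_spectrum(t).values, 1.0)

    def test_zero_case(self):
        t = ReferenceTriplet(m_raw=vis(0.1), bg=vis(0.1), m_std=vis(0.9))
        assert np.allclose(reference_spectrum(t).values, 0.0)

    def test_direct_arithmetic(self):
        # (0.5 - 0.1) / (0.9 - 0.1) = 0.5
        t = ReferenceTriplet(m_raw=vis(0.5), bg=vis(0.1), m_std=vis(0.9))
        assert np.allclose(reference_spectrum(t).values, 0.5)

    def test_scale_invariance_in_standard(self):
        bg = vis(0.1)
        raw = vis(0.5)
        std = vis(0.9)
        base = reference_spectrum(ReferenceTriplet(raw, bg, std))
        k = 3.7  # scale both (Mraw-Bg) and (Mstd-Bg) by the same constant
        raw2 = vis(0.1 + k * 0.4)
        std2 = vis(0.1 + k * 0.8)
        scaled = reference_spectrum(ReferenceTriplet(raw2, bg, std2))
        assert np.allclose(base.values, scaled.values)

    def test_grid_mismatch_rejected(self):
        other = Spectrum(VIS_GRID[:-1], np.full(VIS_GRID.size - 1, 0.5), "visnir")
        with pytest.raises(GridMismatchError):
            ReferenceTriplet(m_raw=other, bg=vis(0.0), m_std=vis(0.9))

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(InvalidReferenceError):
            ReferenceTriplet(m_raw=vis(0.5), bg=vis(0.9), m_std=vis(0.9))


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        # SG(order 2) is exact on quadratics, including truncated edges
        lam = VIS_GRID
        q = 3.0 - 0.01 * (lam - 700.0) + 2e-5 * (lam - 700.0) ** 2
        s = Spectrum(lam, q, "visnir")
        out = savitzky_golay(s, poly_order=2, window=41)
        assert np.allclose(out.values, q, rtol=0, atol=1e-9)

    def test_constant_unchanged(self):
        out = savitzky_golay(vis(2.5), poly_order=2, window=41)
        assert np.allclose(out.values, 2.5)

    def test_noise_suppressed_below_input_rms(self):
        rng = np.random.default_rng(42)
        lam = VIS_GRID
        q = 1.0 + 1e-5 * (lam - 700.0) ** 2
        noisy = q + 0.05 * rng.standard_normal(lam.size)
        out = savitzky_golay(Spectrum(lam, noisy, "visnir"), 2, 41)
        rms_in = np.sqrt(np.mean((noisy - q) ** 2))
        rms_out = np.sqrt(np.mean((out.values - q) ** 2))
        assert rms_out < rms_in

    @pytest.mark.parametrize("window,order", [(40, 2), (3, 3), (5, 5)])
    def test_parameter_errors(self, window, order):
        with pytest.raises(SpectrumError):
            savitzky_golay(vis(1.0), poly_order=order, window=window)

    def test_window_longer_than_grid_rejected(self):
        s = Spectrum(VIS_GRID[:11], np.ones(11), "visnir")
        with pytest.raises(SpectrumError):
            savitzky_golay(s, 2, 41)


class TestMatchingFactor:
    def test_equal_intensities_give_unity(self):
        m = matching_factor(vis(0.7), swir(0.7), 1000.0)
        assert m.factor == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        m = matching_factor(vis(0.8), swir(0.4), 1000.0)
        assert m.factor == pytest.approx(2.0)
        assert m.i_visnir == pytest.approx(0.8)
        assert m.i_swir == pytest.approx(0.4)

    def test_zero_swir_rejected(self):
        with pytest.raises(DegenerateMatchError):
            matching_factor(vis(0.8), swir(0.0), 1000.0)

    def test_factor_identity_enforced_on_type(self):
        with pytest.raises(DegenerateMatchError):
            MatchResult(factor=2.0, i_visnir=0.8, i_swir=0.8)


class TestMergeBands:
    def test_flat_spectra_merge_to_visnir_level(self):
        merged = merge_bands(vis(2.0), swir(1.0), matching_factor(vis(2.0), swir(1.0)))
        assert merged.band == "merged"
        assert np.allclose(merged.values, 2.0)

    def test_zero_junction_discontinuity(self):
        rng = np.random.default_rng(7)
        v = Spectrum(VIS_GRID, 1.0 + 0.3 * rng.random(VIS_GRID.size), "visnir")
        s = Spectrum(SWIR_GRID, 0.5 + 0.2 * rng.random(SWIR_GRID.size), "swir")
        match = matching_factor(v, s)
        merged = merge_bands(v, s, match)
        left = v.interp(1000.0)
        right = merged.interp(1000.0)
        assert abs(left - right) / abs(left) < 1e-12

    def test_grid_is_visnir_below_then_swir_at_and_above(self):
        merged = merge_bands(vis(1.0), swir(1.0))
        assert merged.wavelengths_nm[0] == VIS_GRID[0]
        assert merged.wavelengths_nm[-1] == SWIR_GRID[-1]
        assert np.all(np.diff(merged.wavelengths_nm) > 0)

    def test_band_tag_precondition(self):
        with pytest.raises(SpectrumError):
            merge_bands(swir(1.0), swir(1.0))


class TestResample:
    def test_same_grid_identity(self):
        s = Spectrum(VIS_GRID, np.sin(VIS_GRID / 50.0) + 2, "visnir")
        out = resample(s, VIS_GRID)
        assert np.allclose(out.values, s.values)

    def test_linear_ramp_exact_midpoints(self):
        s = Spectrum([500.0, 600.0, 700.0], [1.0, 2.0, 3.0], "visnir")
        out = resample(s, [550.0, 650.0])
        assert np.allclose(out.values, [1.5, 2.5])

    def test_extrapolation_rejected(self):
        s = Spectrum([500.0, 600.0], [1.0, 2.0], "visnir")
        with pytest.raises(SpectrumError):
            resample(s, [450.0, 550.0])


class TestCsvRoundTrip:
    def test_round_trip_preserves_grid_values_band(self, tmp_path):
        s = Spectrum(SWIR_GRID, 0.1 + 0.9 * np.cos(SWIR_GRID / 90.0) ** 2, "swir")
        path = tmp_path / "s.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path)
        assert back.band == "swir"
        assert np.allclose(back.wavelengths_nm, s.wavelengths_nm)
        assert np.allclose(back.values, s.values, rtol=1e-9)

    def test_band_override(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("wavelength_nm,value\n600,1.0\n700,2.0\n")
        assert read_spectrum_csv(path, band="visnir").band == "visnir"
        with pytest.raises(SpectrumError):
            read_spectrum_csv(path)
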