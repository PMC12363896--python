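"""Spectral metrics: extraction, peak, AUC, centroid, Stokes, scans."""

import numpy as np
import pytest

from eemshift import (EEM, RangeError, Spectrum, UncertaintyBudget, auc,
                      centroid, eem_maxima, emission_spectrum_at,
                      excitation_scan, excitation_spectrum_at, normalize,
                      peak, quadrature_uncertainty, stokes_shift)
from eemshift.synthetic import default_em_grid, default_ex_grid, ideal_eem, \
    medium_preset

from conftest import grid, separable_eem


def spectrum_of(values, wavelengths=None, kind="emission"):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = 800.0 + np.arange(values.size)
    import eemshift
    return Spectrum(eemshift.WavelengthGrid(np.asarray(wavelengths, float)),
                    values, kind)


class TestSpectrumExtraction:
    def test_separable_rows_identical_after_normalization(self, small_eem):
        a = normalize(emission_spectrum_at(small_eem, 770))
        b = normalize(emission_spectrum_at(small_eem, 810))
        assert np.allclose(a.values, b.values)

    def test_nearest_row_snapping(self):
        eem = separable_eem(ex_lo=780, ex_hi=790, ex_step=1)
        spec = emission_spectrum_at(eem, 785.2)
        expected = eem.intensity[np.where(eem.ex_grid.values == 785)[0][0]]
        assert np.array_equal(spec.values, expected)

    def test_tie_snaps_to_lower_wavelength(self):
        eem = separable_eem(em_lo=800, em_hi=802, em_step=0.5)
        col = excitation_spectrum_at(eem, 800.25)
        j = np.where(eem.em_grid.values == 800.0)[0][0]
        assert np.array_equal(col.values, eem.intensity[:, j])

    def test_out_of_range_and_far_snap_rejected(self, small_eem):
        with pytest.raises(RangeError, match="outside grid"):
            emission_spectrum_at(small_eem, 1000.0)
        import eemshift
        ragged = EEM(eemshift.WavelengthGrid(np.array([700.0, 701.0, 705.0])),
                     small_eem.em_grid, np.ones((3, len(small_eem.em_grid))))
        with pytest.raises(RangeError, match="nominal step"):
            emission_spectrum_at(ragged, 703.0)

    def test_rees_band_center_tracks_programmed_law(self):
        fl, _ = medium_preset("bsa")
        eem = ideal_eem(fl, default_ex_grid(), default_em_grid())
        for ex in (770.0, 790.0, 810.0):
            pk, _ = peak(emission_spectrum_at(eem, ex))
            assert abs(pk - fl.band_center(ex)) <= 1.0

    def test_excitation_peak_rises_with_monitored_emission(self):
        """Red-edge emitters show red-shifting excitation maxima, mirroring
        the monitored-emission sequence measured for the albumin sample."""
        fl, _ = medium_preset("bsa")
        eem = ideal_eem(fl, default_ex_grid(), default_em_grid())
        peaks = [peak(excitation_spectrum_at(eem, em))[0]
                 for em in (800, 810, 820, 830, 840)]
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] > peaks[0]


class TestPeak:
    def test_tie_breaks_toward_lower_wavelength(self):
        assert peak(spectrum_of([1, 2, 2, 1])) == (801.0, 2.0)

    def test_symmetric_gaussian_peak_on_grid(self):
        g = grid(700, 950, 0.5)
        vals = np.exp(-((g.values - 826.5) ** 2) / 800.0)
        assert peak(Spectrum(g, vals))[0] == 826.5

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            peak(spectrum_of([np.nan, np.nan, np.nan]))


class TestAuc:
    def test_hand_computed_trapezoid(self):
        assert auc(spectrum_of([0, 1, 2, 1, 0]), 800, 804) == pytest.approx(4.0)

    def test_linearity_and_zero(self):
        s = spectrum_of([0, 1, 2, 1, 0])
        assert auc(normalize(s, "reference_value", reference_value=1 / 3.0),
                   800, 804) == pytest.approx(3 * 4.0)
        assert auc(spectrum_of([0, 0, 0, 0, 0]), 800, 804) == 0.0

    def test_partial_end_intervals_interpolated(self):
        s = spectrum_of([1, 1, 1, 1, 1])
        assert auc(s, 800.5, 803.5) == pytest.approx(3.0)

    def test_additivity_over_adjacent_ranges(self, rng):
        s = spectrum_of(rng.normal(size=41), 800 + 0.5 * np.arange(41))
        total = auc(s, 803.2, 817.9)
        assert auc(s, 803.2, 810.0) + auc(s, 810.0, 817.9) == pytest.approx(
            total, rel=1e-9)

    def test_empty_intersection_rejected(self):
        with pytest.raises(RangeError):
            auc(spectrum_of([1, 2, 3]), 900, 950)


class TestCentroid:
    def test_symmetric_triangle(self):
        assert centroid(spectrum_of([0, 1, 2, 1, 0]), 800, 804) == pytest.approx(802.0)

    def test_right_loaded_mass_in_last_interval(self):
        assert centroid(spectrum_of([0, 0, 0, 0, 4]), 800, 804) > 803.0

    def test_red_tailed_band_centroid_exceeds_peak(self):
        g = grid(700, 1000, 0.5)
        x = g.values
        vals = np.exp(-((x - 820) ** 2) / 800.0) + 0.3 * np.exp(
            -((x - 850) ** 2) / 5000.0)
        s = Spectrum(g, vals)
        # brute-force cumulative-sum oracle
        cum = np.cumsum((vals[1:] + vals[:-1]) / 2 * np.diff(x))
        k = np.searchsorted(cum, cum[-1] / 2)
        lo = x[k] + (x[k + 1] - x[k]) * 0  # bracketing grid point
        c = centroid(s, 700, 1000)
        assert c > peak(s)[0]
        assert abs(c - lo) <= 1.0

    def test_scaling_invariance(self):
        s = spectrum_of([0.0, 1, 3, 2, 1, 0])
        s3 = s.replace_values(3.0 * s.values)
        assert centroid(s, 800, 805) == pytest.approx(centroid(s3, 800, 805))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            centroid(spectrum_of([0, -1, -2, -1, 0]), 800, 804)


class TestEEMMaxima:
    def test_single_nonzero_cell(self):
        g = grid(700, 704, 1)
        m = np.zeros((5, 5))
        m[3, 1] = 7.0
        assert eem_maxima(EEM(g, g, m)) == (703.0, 701.0, 7.0)

    def test_separable_factorizes(self, small_eem):
        ex, em, _ = eem_maxima(small_eem)
        i = np.argmax(small_eem.intensity.max(axis=1))
        j = np.argmax(small_eem.intensity.max(axis=0))
        assert (ex, em) == (small_eem.ex_grid.values[i], small_eem.em_grid.values[j])

    def test_solvent_preset_maxima_and_stokes(self):
        fl, _ = medium_preset("dmso")
        eem = ideal_eem(fl, default_ex_grid(), default_em_grid())
        ex, em, _ = eem_maxima(eem)
        assert (ex, em) == (792.0, 826.5)
        assert stokes_shift(ex, em) == pytest.approx(34.5)


class TestStokesAndUncertainty:
    @pytest.mark.parametrize("ex,em,expected", [
        (792.0, 826.5, 34.5), (794.0, 813.5, 19.5), (809.0, 823.5, 14.5)])
    def test_stokes_shift_values(self, ex, em, expected):
        assert stokes_shift(ex, em) == pytest.approx(expected)

    def test_negative_shift_warns(self):
        with pytest.warns(UserWarning, match="negative Stokes"):
            assert stokes_shift(800.0, 790.0) == pytest.approx(-10.0)

    def test_quadrature_values(self):
        assert round(quadrature_uncertainty(1, 1), 1) == 1.4
        assert quadrature_uncertainty(0, 0.7) == pytest.approx(0.7)
        assert quadrature_uncertainty(3, 4) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            quadrature_uncertainty(-1, 1)

    def test_budget_combines_in_quadrature(self):
        b = UncertaintyBudget(1.0, 1.0)
        assert b.u_stokes == pytest.approx(np.sqrt(2.0), abs=1e-9)


class TestNormalize:
    def test_max_mode_reaches_unity(self):
        s = normalize(spectrum_of([1, 4, 2.0]))
        assert s.values.max() == 1.0

    def test_reference_equal_to_max_matches_max_mode(self):
        s = spectrum_of([1, 4, 2.0])
        a = normalize(s, "max")
        b = normalize(s, "reference_value", reference_value=4.0)
        assert np.allclose(a.values, b.values)

    def test_shared_reference_preserves_auc_ratio(self):
        s1 = spectrum_of([0, 2, 4, 2, 0])
        s2 = spectrum_of([0, 1, 2, 1, 0])
        ratio = auc(s1, 800, 804) / auc(s2, 800, 804)
        n1 = normalize(s1, "reference_value", reference_value=5.0)
        n2 = normalize(s2, "reference_value", reference_value=5.0)
        assert auc(n1, 800, 804) / auc(n2, 800, 804) == pytest.approx(ratio)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            normalize(spectrum_of([0, 0, 0.0]))


class TestExcitationScan:
    def test_separable_scan_constant_peak_and_centroid(self, small_eem):
        scan = excitation_scan(small_eem, [770, 780, 790, 800, 810],
                               auc_lo=700, auc_hi=950)
        assert scan.table["peak_nm"].nunique() == 1
        assert np.ptp(scan.table["centroid_nm"].to_numpy()) < 1e-9
        assert scan.table["auc_ratio"].max() == 1.0

    def test_rees_scan_has_monotone_peak_column(self):
        fl, _ = medium_preset("bsa")
        eem = ideal_eem(fl, default_ex_grid(), default_em_grid())
        scan = excitation_scan(eem, [770, 780, 790, 800, 810])
        peaks = scan.table["peak_nm"].to_numpy()
        assert np.all(np.diff(peaks) > 0)

    def test_single_excitation_ratios_are_unity(self, small_eem):
        scan = excitation_scan(small_eem, [790.0], auc_lo=700, auc_hi=950)
        assert scan.table["peak_intensity_ratio"].iloc[0] == 1.0
        assert scan.table["auc_ratio"].iloc[0] == 1.0

    def test_permutation_equivariance(self, small_eem):
        fwd = excitation_scan(small_eem, [770, 790, 810], auc_lo=700, auc_hi=950)
        rev = excitation_scan(small_eem, [810, 790, 770], auc_lo=700, auc_hi=950)
        cols = ["excitation_nm", "peak_nm", "centroid_nm", "auc"]
        a = fwd.table[cols].sort_values("excitation_nm").to_numpy()
        b = rev.table[cols].sort_values("excitation_nm").to_numpy()
        assert np.allclose(a, b)

    def test_report_table_rounding(self, small_eem):
        t = excitation_scan(small_eem, [770, 790], auc_lo=700, auc_hi=950).to_report_table()
        assert np.all(np.mod(t["peak_nm"] * 2, 1) == 0)  # 0.5 nm rounding
        assert np.all(np.mod(t["centroid_nm"] * 2, 1) == 0)
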