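"""FT-IR pipeline: IO, correction, averaging, normalization, deconvolution."""

import math

import numpy as np
import pytest

from methylscope import ftir
from methylscope.ftir import (
    GAUSS_AREA_FACTOR,
    BandFitResult,
    FitConvergenceError,
    PipelineOrderError,
    Spectrum,
    SpectrumFormatError,
    SpectrumState,
    absorbance_at,
    assign_band,
    average_spectra,
    band_statistics_table,
    baseline_correct,
    bend_cytosine_ratio,
    detect_peaks,
    extract_window,
    fit_gaussian_peaks,
    gaussian_profile,
    normalize_max,
    qc_report,
    read_spectrum,
    write_spectrum_csv,
    write_spectrum_jcamp,
)
from methylscope.synthetic import (
    BandSpec,
    SpectrumSimParams,
    generate_ftir_spectrum,
)

CORRECTED = SpectrumState.BASELINE_CORRECTED


def corrected(wavenumbers, absorbances):
    return Spectrum(wavenumbers, absorbances, CORRECTED)


@pytest.fixture
def default_spectrum(band_library):
    return generate_ftir_spectrum(SpectrumSimParams(bands=band_library))


@pytest.fixture
def default_normalized(default_spectrum):
    return normalize_max(baseline_correct(default_spectrum))


class TestIO:
    def test_csv_round_trip_701_rows(self, tmp_path, default_spectrum):
        path = tmp_path / "s.csv"
        write_spectrum_csv(default_spectrum, path)
        back = read_spectrum(path)
        assert len(back) == 701
        assert back.state is SpectrumState.RAW
        np.testing.assert_allclose(back.absorbances,
                                   default_spectrum.absorbances, atol=1e-9)

    def test_non_numeric_cell_names_the_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = [f"{3600 - 4 * i},0.1" for i in range(10)]
        rows[4] = "3584,oops"
        path.write_text("wavenumber,absorbance\n" + "\n".join(rows) + "\n")
        with pytest.raises(SpectrumFormatError, match="line 6"):
            read_spectrum(path)

    def test_jcamp_round_trip(self, tmp_path, default_spectrum):
        path = tmp_path / "s.jdx"
        write_spectrum_jcamp(default_spectrum, path)
        back = read_spectrum(path, format="jcamp")
        np.testing.assert_allclose(back.wavenumbers,
                                   default_spectrum.wavenumbers, atol=1e-9)
        np.testing.assert_allclose(back.absorbances,
                                   default_spectrum.absorbances, atol=1e-6)

    def test_ascending_input_is_resorted_descending(self, tmp_path):
        path = tmp_path / "asc.csv"
        path.write_text("".join(f"{800 + 4 * i},{0.1 * i}\n" for i in range(10)))
        s = read_spectrum(path)
        assert s.wavenumbers[0] > s.wavenumbers[-1]

    def test_duplicate_wavenumbers_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        rows = [f"{3600 - 4 * i},0.1" for i in range(10)] + ["3600,0.2"]
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(SpectrumFormatError, match="duplicate"):
            read_spectrum(path)


class TestSpectrumContainer:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            Spectrum(np.arange(5, 0, -1.0), np.zeros(5))

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            Spectrum(np.arange(8.0), np.zeros(8))

    def test_normalized_state_requires_unit_maximum(self):
        w = 3600.0 - 4.0 * np.arange(10)
        with pytest.raises(ValueError, match="max absorbance 1"):
            Spectrum(w, np.full(10, 0.5), SpectrumState.NORMALIZED)


class TestBaseline:
    def test_line_through_anchors_maps_to_zero(self, instrument_grid):
        w = instrument_grid
        s = Spectrum(w, 0.1 + 2e-5 * w)
        out = baseline_correct(s)
        np.testing.assert_allclose(out.absorbances, 0.0, atol=1e-12)
        assert out.state is CORRECTED

    def test_offset_invariance(self, band_library, instrument_grid):
        s = generate_ftir_spectrum(SpectrumSimParams(bands=band_library))
        shifted = Spectrum(s.wavenumbers, s.absorbances + 0.37)
        np.testing.assert_allclose(
            baseline_correct(s).absorbances,
            baseline_correct(shifted).absorbances, atol=1e-12)

    def test_linear_drift_removed_from_single_band(self, instrument_grid):
        band = BandSpec(center=2935.0, height=0.5, fwhm=30.0)
        s = generate_ftir_spectrum(SpectrumSimParams(
            bands=(band,), baseline_coeffs=(0.3, -5e-5)))
        out = baseline_correct(s)
        pure = gaussian_profile(out.wavenumbers, 2935.0, 0.5, 30.0)
        np.testing.assert_allclose(out.absorbances, pure, atol=1e-6)

    def test_fewer_than_four_anchors_rejected(self, default_spectrum):
        with pytest.raises(ValueError, match="4 anchor"):
            baseline_correct(default_spectrum, anchors=(3600, 1800, 800))

    def test_anchor_outside_range_rejected(self, default_spectrum):
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(default_spectrum, anchors=(3700, 2700, 1800, 800))

    def test_correcting_twice_is_an_order_error(self, default_spectrum):
        once = baseline_correct(default_spectrum)
        with pytest.raises(PipelineOrderError):
            baseline_correct(once)


class TestAverage:
    def test_average_of_one_is_itself(self, default_spectrum):
        c = baseline_correct(default_spectrum)
        out = average_spectra([c])
        np.testing.assert_array_equal(out.absorbances, c.absorbances)
        assert out.state is SpectrumState.AVERAGED

    def test_average_of_s_and_minus_s_is_zero(self, instrument_grid):
        y = np.sin(instrument_grid / 100.0)
        s = corrected(instrument_grid, y)
        minus = corrected(instrument_grid, -y)
        out = average_spectra([s, minus])
        np.testing.assert_allclose(out.absorbances, 0.0, atol=1e-15)

    def test_thirteen_replicates_average_toward_template(self, instrument_grid):
        """Noise on the mean of 13 replicates shrinks like sigma/sqrt(13)."""
        sigma = 0.01
        template = gaussian_profile(instrument_grid, 2935.0, 0.5, 30.0)
        rng = np.random.default_rng(20260930)
        reps = [corrected(instrument_grid,
                          template + rng.normal(0, sigma, template.shape))
                for _ in range(13)]
        out = average_spectra(reps)
        dev = out.absorbances - template
        se = sigma / math.sqrt(13)
        assert np.sqrt(np.mean(dev ** 2)) < 1.5 * se
        for target in (2935.0, 2000.0, 1000.0):
            i = np.argmin(np.abs(instrument_grid - target))
            assert abs(dev[i]) < 3 * se

    def test_grid_mismatch_reported(self, instrument_grid):
        a = corrected(instrument_grid, np.zeros(701))
        other = instrument_grid[:-1]
        b = corrected(other, np.zeros(700))
        with pytest.raises(ValueError, match="positions \\[1\\]"):
            average_spectra([a, b])

    def test_raw_input_is_an_order_error(self, default_spectrum):
        with pytest.raises(PipelineOrderError):
            average_spectra([default_spectrum])


class TestNormalize:
    def test_maximum_is_exactly_one(self, default_spectrum):
        out = normalize_max(baseline_correct(default_spectrum))
        assert abs(out.absorbances.max() - 1.0) <= 1e-12
        assert out.state is SpectrumState.NORMALIZED

    def test_idempotence(self, default_normalized):
        again = normalize_max(default_normalized)
        np.testing.assert_array_equal(again.absorbances,
                                      default_normalized.absorbances)

    def test_global_maximum_in_nh_region(self, default_normalized):
        peak_w = default_normalized.wavenumbers[
            np.argmax(default_normalized.absorbances)]
        assert 3395.0 <= peak_w <= 3425.0

    def test_degenerate_spectrum_rejected(self, instrument_grid):
        flat_zero = corrected(instrument_grid, np.zeros(701))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_max(flat_zero)

    def test_raw_input_is_an_order_error(self, default_spectrum):
        with pytest.raises(PipelineOrderError):
            normalize_max(default_spectrum)


class TestWindow:
    def test_ch3_window_has_36_grid_points(self, default_normalized):
        win = extract_window(default_normalized, 2992.0, 2850.0)
        assert len(win) == 36
        assert win.wavenumbers[0] == 2992.0 and win.wavenumbers[-1] == 2852.0

    def test_full_range_window_is_identity(self, default_normalized):
        win = extract_window(default_normalized, 3600.0, 800.0)
        np.testing.assert_array_equal(win.absorbances,
                                      default_normalized.absorbances)

    def test_inverted_bounds_rejected(self, default_normalized):
        with pytest.raises(ValueError):
            extract_window(default_normalized, 2850.0, 2992.0)


class TestDetectPeaks:
    def test_single_gaussian_one_candidate_near_center(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        guesses = detect_peaks(s, "low")
        assert len(guesses) == 1
        assert abs(guesses[0].center - 2935.0) <= 4.0

    def test_two_resolved_gaussians_two_candidates(self, ch3_grid):
        y = (gaussian_profile(ch3_grid, 2900.0, 0.5, 20.0)
             + gaussian_profile(ch3_grid, 2960.0, 0.4, 20.0))
        assert len(detect_peaks(corrected(ch3_grid, y), "low")) == 2

    def test_flat_spectrum_yields_no_candidates(self, ch3_grid):
        assert detect_peaks(corrected(ch3_grid, np.full(36, 0.3)), "low") == []

    def test_unknown_sensitivity_rejected(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        with pytest.raises(ValueError, match="sensitivity"):
            detect_peaks(s, "ultra")


class TestFit:
    def test_single_gaussian_recovered_to_1e6(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        fit = fit_gaussian_peaks(s, detect_peaks(s, "low"))
        assert fit.n_peaks == 1
        p = fit.peaks[0]
        assert p.center == pytest.approx(2935.0, rel=1e-6)
        assert p.height == pytest.approx(0.5, rel=1e-6)
        assert p.fwhm == pytest.approx(30.0, rel=1e-6)
        assert fit.total_area == pytest.approx(0.5 * 30.0 * GAUSS_AREA_FACTOR,
                                               rel=1e-6)
        assert fit.total_area == pytest.approx(15.967, abs=1e-3)

    def test_two_gaussian_sum_area_matches_analytic(self, ch3_grid):
        comps = [(2900.0, 0.6, 22.0), (2958.0, 0.35, 18.0)]
        y = sum(gaussian_profile(ch3_grid, *c) for c in comps)
        s = corrected(ch3_grid, y)
        fit = fit_gaussian_peaks(s, detect_peaks(s, "medium"))
        analytic = sum(h * f * GAUSS_AREA_FACTOR for _, h, f in comps)
        assert fit.total_area == pytest.approx(analytic, rel=1e-4)

    def test_areas_scale_linearly_with_absorbance(self, ch3_grid):
        y = gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0)
        full = fit_gaussian_peaks(corrected(ch3_grid, y),
                                  detect_peaks(corrected(ch3_grid, y), "low"))
        half_s = corrected(ch3_grid, 0.5 * y)
        half = fit_gaussian_peaks(half_s, detect_peaks(half_s, "low"))
        assert half.total_area == pytest.approx(0.5 * full.total_area, rel=1e-6)

    def test_main_peak_is_largest_area(self, ch3_grid):
        comps = [(2900.0, 0.6, 22.0), (2958.0, 0.35, 18.0)]
        y = sum(gaussian_profile(ch3_grid, *c) for c in comps)
        s = corrected(ch3_grid, y)
        fit = fit_gaussian_peaks(s, detect_peaks(s, "medium"))
        assert fit.main_peak_frequency == pytest.approx(2900.0, abs=0.5)
        assert fit.main_peak_area <= fit.total_area

    def test_no_initial_guess_rejected(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        with pytest.raises(ValueError, match="initial peak guess"):
            fit_gaussian_peaks(s, [])

    def test_exhausted_budget_raises_with_diagnostics(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        with pytest.raises(FitConvergenceError) as err:
            fit_gaussian_peaks(s, detect_peaks(s, "low"), max_nfev=1)
        assert "cost" in err.value.diagnostics


class TestSummaryTable:
    def test_three_dose_groups_decreasing_total_area(self, band_library):
        fits = []
        for label, level in [("control", 1.0), ("vpa_1mM", 0.6),
                             ("vpa_20mM", 0.3)]:
            s = generate_ftir_spectrum(SpectrumSimParams(
                methylation_level=level, bands=band_library))
            win = extract_window(normalize_max(baseline_correct(s)),
                                 2992.0, 2850.0)
            fits.append((label, fit_gaussian_peaks(win, detect_peaks(win, "low"))))
        table = band_statistics_table(fits)
        areas = table["total_area"].to_numpy()
        assert areas[0] > areas[1] > areas[2]
        assert list(table.columns) == ["group", "n_peaks", "main_peak_frequency",
                                       "main_peak_area", "total_area"]

    def test_single_group_single_row(self, ch3_grid):
        s = corrected(ch3_grid, gaussian_profile(ch3_grid, 2935.0, 0.5, 30.0))
        fit = fit_gaussian_peaks(s, detect_peaks(s, "low"))
        assert len(band_statistics_table({"only": fit})) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no fit results"):
            band_statistics_table({})


class TestPointAbsorbance:
    def test_on_grid_target_returns_that_sample(self, instrument_grid):
        s = corrected(instrument_grid, instrument_grid * 1e-4)
        assert absorbance_at(s, 1492.0) == pytest.approx(0.1492)

    def test_tie_resolves_to_higher_wavenumber(self, instrument_grid):
        s = corrected(instrument_grid, instrument_grid * 1e-4)
        # 1374 is midway between grid points 1376 and 1372
        assert absorbance_at(s, 1374.0) == pytest.approx(0.1376)

    def test_flat_spectrum_constant_everywhere(self, instrument_grid):
        s = corrected(instrument_grid, np.full(701, 0.7))
        for target in (3600.0, 1375.0, 803.0):
            assert absorbance_at(s, target) == 0.7

    def test_out_of_range_rejected(self, instrument_grid):
        s = corrected(instrument_grid, np.full(701, 0.7))
        with pytest.raises(ValueError, match="outside"):
            absorbance_at(s, 700.0)


class TestBendCytosineRatio:
    # Reported reference ratios for DNA of VPA-treated vs untreated HeLa
    # cells: 20 mM 1.3799, 1 mM 1.2034, control 1.3224. Kept here for
    # orientation only — the original spectra are unavailable, so these are
    # not computed targets.

    def test_flat_spectrum_ratio_is_one(self, instrument_grid):
        s = corrected(instrument_grid, np.full(701, 0.7))
        assert bend_cytosine_ratio(s) == pytest.approx(1.0)

    def test_two_to_one_band_heights_give_ratio_two(self, instrument_grid):
        y = (gaussian_profile(instrument_grid, 1375.0, 0.5, 20.0)
             + gaussian_profile(instrument_grid, 1492.0, 0.25, 20.0))
        s = corrected(instrument_grid, y)
        assert bend_cytosine_ratio(s) == pytest.approx(2.0, rel=0.05)

    def test_direction_is_parameterizable(self, instrument_grid):
        y = (gaussian_profile(instrument_grid, 1375.0, 0.5, 20.0)
             + gaussian_profile(instrument_grid, 1492.0, 0.25, 20.0))
        s = corrected(instrument_grid, y)
        fwd = bend_cytosine_ratio(s)
        inv = bend_cytosine_ratio(s, numerator=1492.0, denominator=1375.0)
        assert fwd * inv == pytest.approx(1.0)

    def test_zero_denominator_rejected(self, instrument_grid):
        y = np.zeros(701)
        y[np.argmin(np.abs(instrument_grid - 1375.0))] = 0.5
        s = corrected(instrument_grid, y)
        with pytest.raises(ZeroDivisionError):
            bend_cytosine_ratio(s)


class TestQc:
    def test_default_library_passes_quality_checks(self, default_normalized):
        qc = qc_report(default_normalized)
        assert qc.bform_marker_present
        assert qc.shoulder_1707_present
        assert qc.ps_below_pas

    def test_removing_1225_band_ablates_bform_marker(self, band_library):
        reduced = tuple(b for b in band_library if b.center != 1225.0)
        s = generate_ftir_spectrum(SpectrumSimParams(bands=reduced))
        qc = qc_report(normalize_max(baseline_correct(s)))
        assert not qc.bform_marker_present

    def test_flat_spectrum_fails_all_checks(self, instrument_grid):
        qc = qc_report(corrected(instrument_grid, np.full(701, 0.5)))
        assert not qc.bform_marker_present
        assert not qc.shoulder_1707_present
        assert not qc.ps_below_pas

    def test_insufficient_coverage_rejected(self, ch3_grid):
        s = corrected(ch3_grid, np.full(36, 0.5))
        with pytest.raises(ValueError, match="cover"):
            qc_report(s)


class TestAssignBand:
    @pytest.mark.parametrize("wavenumber,label", [
        (2935.0, "C-H stretch (-CH3)"),
        (1661.0, "thymine/adenine"),
        (3410.0, "NH/NH2 stretch"),
        (1375.0, "CH3 bend"),
        (1228.0, "nu_as PO2- (B-form)"),
        (1080.0, "nu_s PO2-"),
        (900.0, "unassigned"),
    ])
    def test_assignment_lookup(self, wavenumber, label):
        assert assign_band(wavenumber) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_band(4000.0)
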