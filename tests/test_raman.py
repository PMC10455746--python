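"""Raman pipeline: preprocessing, band quantification, crystallinity fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaffoldlab import raman
from scaffoldlab import synthetic_data as synth
from scaffoldlab.raman import (
    FWHM_PER_SIGMA,
    PeakDefinition,
    PipelineConfig,
    RamanSpectrum,
    SpectrumSet,
)


def spectrum(axis, intensity, **meta):
    return RamanSpectrum(axis=np.asarray(axis, float), intensity=np.asarray(intensity, float), meta=meta)


def two_band_model(a960=200.0, a1244=50.0, sigma960=8.0, noise=0.0, seed=0):
    return synth.SpectrumModel(
        bands=(
            synth.BandSpec("ha_960", 960.0, a960, sigma960),
            synth.BandSpec("amide3_1244", 1244.0, a1244, 12.0),
        ),
        noise_sd=noise,
        seed=seed,
    )


class TestSpectrumIO:
    def test_write_read_round_trip(self, tmp_path, noiseless_spectrum_model):
        spec = synth.gen_spectrum(noiseless_spectrum_model)
        path = tmp_path / "spec.txt"
        raman.write_spectrum(spec, path)
        back = raman.read_spectrum(path)
        np.testing.assert_allclose(back.axis, spec.axis, atol=1e-6)
        np.testing.assert_allclose(back.intensity, spec.intensity, rtol=1e-6)

    def test_descending_axis_sorted_on_read(self, tmp_path):
        path = tmp_path / "desc.txt"
        path.write_text("1000 3.0\n900 1.0\n950 2.0\n")
        spec = raman.read_spectrum(path)
        np.testing.assert_array_equal(spec.axis, [900, 950, 1000])
        np.testing.assert_array_equal(spec.intensity, [1.0, 2.0, 3.0])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("# only a comment\n")
        with pytest.raises(ValueError, match="2 data rows"):
            raman.read_spectrum(path)

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("900 1.0\n950 oops\n")
        with pytest.raises(ValueError, match=":2:"):
            raman.read_spectrum(path)

    def test_comma_separated_accepted(self, tmp_path):
        path = tmp_path / "csv.txt"
        path.write_text("900,1.0\n950,2.0\n")
        spec = raman.read_spectrum(path)
        assert spec.intensity[1] == 2.0


class TestSubtractBackground:
    def test_self_subtraction_zero(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        out = raman.subtract_background(spec, spec)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_constant_background_shifts(self):
        x = np.arange(600.0, 700.0)
        spec = spectrum(x, np.ones_like(x) * 5)
        bg = spectrum(x, np.ones_like(x) * 2)
        out = raman.subtract_background(spec, bg)
        np.testing.assert_allclose(out.intensity, 3.0)

    def test_disjoint_axes_rejected(self):
        a = spectrum([600, 601, 602], [1, 1, 1])
        b = spectrum([1700, 1701], [1, 1])
        with pytest.raises(ValueError, match="overlap"):
            raman.subtract_background(a, b)


class TestBaseline:
    def test_pure_polynomial_removed(self):
        x = np.arange(600.0, 1801.0)
        y = 5.0 + 0.02 * x - 1e-5 * x**2 + 3e-9 * x**3
        out = raman.baseline_correct(spectrum(x, y), method="modpoly", order=3)
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(np.abs(y))
        assert out.meta["baseline_converged"]

    def test_peak_height_preserved(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        out = raman.baseline_correct(spec, method="modpoly", order=3)
        height = raman.peak_intensity(out, PeakDefinition("ha", 960.0))
        assert height == pytest.approx(100.0, rel=0.02)

    def test_linear_ramp_invariance(self, noiseless_spectrum_model):
        """Adding a ramp changes corrected band heights by < 2 %."""
        flat = synth.gen_spectrum(noiseless_spectrum_model)
        ramped = flat.with_intensity(flat.intensity + 0.05 * (flat.axis - 600.0))
        out_flat = raman.baseline_correct(flat)
        out_ramp = raman.baseline_correct(ramped)
        for band in raman.DEFAULT_BANDS.values():
            h0 = raman.peak_intensity(out_flat, band)
            h1 = raman.peak_intensity(out_ramp, band)
            assert h1 == pytest.approx(h0, rel=0.02)

    def test_endpoint_linear(self):
        x = np.arange(900.0, 1001.0)
        y = 2.0 + 0.1 * (x - 900.0)
        out = raman.baseline_correct(spectrum(x, y), method="endpoint_linear")
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline method"):
            raman.baseline_correct(spectrum([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0]), method="nope")


def sg_oracle(y, order, window):
    """Brute-force per-point windowed least-squares polynomial smoother."""
    n = y.size
    half = window // 2
    out = np.empty(n)
    idx = np.arange(window)
    # interior: centered window, evaluated at its center
    for i in range(half, n - half):
        c = np.polyfit(idx, y[i - half : i + half + 1], order)
        out[i] = np.polyval(c, half)
    # edges: polynomial fitted to the terminal window, evaluated at the edge points
    c_first = np.polyfit(idx, y[:window], order)
    for i in range(half):
        out[i] = np.polyval(c_first, i)
    c_last = np.polyfit(idx, y[-window:], order)
    for i in range(n - half, n):
        out[i] = np.polyval(c_last, i - (n - window))
    return out


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        x = np.arange(600.0, 700.0)
        y = 1.0 + 0.3 * x + 0.002 * x**2
        out = raman.smooth_sg(spectrum(x, y))
        np.testing.assert_allclose(out.intensity, y, rtol=1e-9)

    def test_matches_windowed_polyfit_oracle(self, rng):
        """Order-2 / 7-point smoothing equals the direct per-point LS oracle."""
        x = np.arange(600.0, 800.0)
        y = rng.normal(size=x.size) * 10 + np.sin(x / 30) * 50
        out = raman.smooth_sg(spectrum(x, y), order=2, window=7)
        np.testing.assert_allclose(out.intensity, sg_oracle(y, 2, 7), atol=1e-10)

    def test_noise_variance_reduced(self, rng):
        x = np.arange(600.0, 1100.0)
        y = rng.normal(0.0, 1.0, size=x.size)
        out = raman.smooth_sg(spectrum(x, y))
        assert out.intensity.var() < y.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            raman.smooth_sg(spectrum(np.arange(10.0), np.zeros(10)), window=6)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            raman.smooth_sg(spectrum(np.arange(5.0), np.zeros(5)), window=7)


class TestPeakIntensity:
    def test_noiseless_amplitude(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        assert raman.peak_intensity(spec, PeakDefinition("ha", 960.0)) == pytest.approx(100.0, rel=1e-6)

    def test_all_zero_spectrum(self):
        x = np.arange(900.0, 1001.0)
        assert raman.peak_intensity(spectrum(x, np.zeros_like(x)), PeakDefinition("ha", 960.0)) == 0.0

    def test_off_center_band_recovered(self):
        """A 3 cm^-1 calibration shift is absorbed by the ±5 cm^-1 window."""
        model = synth.SpectrumModel(bands=(synth.BandSpec("ha", 963.0, 100.0, 8.0),))
        spec = synth.gen_spectrum(model)
        assert raman.peak_intensity(spec, PeakDefinition("ha", 960.0, half_window=5.0)) == pytest.approx(
            100.0, rel=1e-6
        )

    def test_window_outside_axis_rejected(self):
        x = np.arange(600.0, 700.0)
        with pytest.raises(ValueError, match="outside"):
            raman.peak_intensity(spectrum(x, np.zeros_like(x)), PeakDefinition("ha", 960.0))


class TestRatios:
    def test_equal_amplitudes_unit_carbonate_ratio(self):
        model = synth.SpectrumModel(
            bands=(
                synth.BandSpec("ha_960", 960.0, 80.0, 6.0),
                synth.BandSpec("carbonate_1070", 1070.0, 80.0, 6.0),
                synth.BandSpec("phe_1004", 1004.0, 40.0, 5.0),
                synth.BandSpec("amide3_1244", 1244.0, 40.0, 12.0),
                synth.BandSpec("pla_874", 874.0, 40.0, 7.0),
                synth.BandSpec("po_971", 971.0, 1.0, 7.0),
                synth.BandSpec("nu_po_1091", 1091.0, 40.0, 8.0),
                synth.BandSpec("p_o_1374", 1374.0, 40.0, 10.0),
            )
        )
        m = raman.compute_ratios(synth.gen_spectrum(model))
        assert m.carbonate_ha == pytest.approx(1.0, rel=0.02)

    def test_amide_ratio_from_ground_truth(self):
        spec = synth.gen_spectrum(two_band_model(a960=200.0, a1244=50.0))
        bands = {
            "pla_874": PeakDefinition("pla_874", 874.0),
            "ha_960": PeakDefinition("ha_960", 960.0),
            "phe_1004": PeakDefinition("phe_1004", 1004.0),
            "carbonate_1070": PeakDefinition("carbonate_1070", 1070.0),
            "amide3_1244": PeakDefinition("amide3_1244", 1244.0),
        }
        # isolated bands: intensity ratio equals the amplitude ratio
        i960 = raman.peak_intensity(spec, bands["ha_960"])
        i1244 = raman.peak_intensity(spec, bands["amide3_1244"])
        assert i960 / i1244 == pytest.approx(4.0, rel=1e-3)

    def test_doubling_ha_band_scales_ratios(self):
        m1 = raman.compute_ratios(synth.gen_spectrum(
            synth.SpectrumModel(bands=synth.default_bands(ha=200.0))))
        m2 = raman.compute_ratios(synth.gen_spectrum(
            synth.SpectrumModel(bands=synth.default_bands(ha=400.0))))
        # overlapping 971 band contributes to the 960 window, so the scaling
        # is approximate rather than an exact factor of two
        assert m2.ha_phe > m1.ha_phe * 1.5
        assert m2.carbonate_ha < m1.carbonate_ha * 0.7

    def test_zero_denominator_names_band(self):
        x = np.arange(600.0, 1801.0)
        with pytest.raises(ZeroDivisionError, match="phe_1004"):
            raman.compute_ratios(spectrum(x, np.zeros_like(x)))

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, derandomize=True)
    def test_intensity_scale_equivariance(self, scale):
        """Global intensity rescaling leaves all ratios unchanged."""
        spec = synth.gen_spectrum(synth.SpectrumModel(bands=synth.default_bands()))
        m1 = raman.compute_ratios(spec)
        m2 = raman.compute_ratios(spec.with_intensity(spec.intensity * scale))
        assert m2.ha_phe == pytest.approx(m1.ha_phe, rel=1e-9)
        assert m2.carbonate_ha == pytest.approx(m1.carbonate_ha, rel=1e-9)
        assert m2.ha_amide3 == pytest.approx(m1.ha_amide3, rel=1e-9)


class TestApatiteFit:
    def test_noiseless_closed_form_fwhm(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        fit = raman.fit_apatite_gaussian(spec)
        assert fit.converged
        assert fit.fwhm == pytest.approx(FWHM_PER_SIGMA * 8.0, rel=1e-6)  # 18.8386 cm^-1
        assert fit.inv_fwhm == pytest.approx(1.0 / (FWHM_PER_SIGMA * 8.0), rel=1e-6)  # 0.05308 cm
        assert fit.mu == pytest.approx(960.0, abs=1e-3)

    def test_offset_invariance(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        shifted = spec.with_intensity(spec.intensity + 50.0)
        f0 = raman.fit_apatite_gaussian(spec)
        f1 = raman.fit_apatite_gaussian(shifted)
        assert f1.fwhm == pytest.approx(f0.fwhm, rel=1e-6)
        assert f1.offset == pytest.approx(f0.offset + 50.0, abs=1e-3)

    def test_monte_carlo_recovery_at_2pct_noise(self):
        """Mean recovered FWHM over 100 seeds within 2 % of truth at 2 % noise."""
        true_fwhm = FWHM_PER_SIGMA * 8.0
        fwhms = []
        for seed in range(100):
            model = synth.SpectrumModel(
                bands=(synth.BandSpec("ha_960", 960.0, 100.0, 8.0),),
                noise_sd=2.0, seed=seed,
            )
            fit = raman.fit_apatite_gaussian(synth.gen_spectrum(model))
            assert fit.converged
            fwhms.append(fit.fwhm)
        assert np.mean(fwhms) == pytest.approx(true_fwhm, rel=0.02)

    def test_too_few_points_rejected(self):
        x = np.linspace(900.0, 1000.0, 5)
        with pytest.raises(ValueError, match=">= 8 points"):
            raman.fit_apatite_gaussian(spectrum(x, np.zeros_like(x)))

    def test_flat_spectrum_flagged(self):
        x = np.arange(850.0, 1050.0)
        fit = raman.fit_apatite_gaussian(spectrum(x, np.ones_like(x)))
        assert not fit.converged


class TestMeanSpectrum:
    def test_singleton(self, single_band_model):
        spec = synth.gen_spectrum(single_band_model)
        out = raman.mean_spectrum(SpectrumSet(spectra=(spec,)))
        np.testing.assert_allclose(out.intensity, spec.intensity)

    def test_mirrored_pair_gives_constant(self):
        x = np.arange(600.0, 700.0)
        a = spectrum(x, 5.0 + np.sin(x / 5))
        b = spectrum(x, 5.0 - np.sin(x / 5))
        out = raman.mean_spectrum([a, b])
        np.testing.assert_allclose(out.intensity, 5.0, atol=1e-12)

    def test_clt_bound_on_jittered_set(self):
        n, jitter, amp = 148, 0.05, 200.0
        sset = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=(synth.BandSpec("ha_960", 960.0, amp, 8.0),), seed=11),
            n, jitter=jitter,
        )
        mean = raman.mean_spectrum(sset)
        peak = raman.peak_intensity(mean, PeakDefinition("ha", 960.0))
        assert abs(peak - amp) < 3 * jitter * amp / math.sqrt(n)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            raman.mean_spectrum([])


class TestSetMetrics:
    def test_noiseless_homogeneous_sd_zero(self):
        sset = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=synth.default_bands()), 5, jitter=0.0
        )
        per_spec, summary, n_failed = raman.set_metrics(sset)
        assert n_failed == 0
        ratios = summary[summary.metric.isin(["ha_phe", "carbonate_ha", "inv_fwhm"])]
        assert (ratios["sd"].abs() < 1e-9).all()

    def test_osteogenic_direction(self):
        """A stronger apatite band (osteogenic set) lowers carbonate/HA and
        raises the mineral-to-matrix ratios relative to control."""
        co = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=synth.default_bands(ha=200.0), noise_sd=2.0, seed=1),
            20, jitter=0.05, label="CO",
        )
        ob = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=synth.default_bands(ha=300.0), noise_sd=2.0, seed=2),
            20, jitter=0.05, label="OB",
        )
        _, s_co, _ = raman.set_metrics(co)
        _, s_ob, _ = raman.set_metrics(ob)
        get = lambda s, m: float(s.set_index("metric").loc[m, "mean"])  # noqa: E731
        assert get(s_ob, "carbonate_ha") < get(s_co, "carbonate_ha")
        assert get(s_ob, "ha_phe") > get(s_co, "ha_phe")
        assert get(s_ob, "ha_amide3") > get(s_co, "ha_amide3")

    def test_narrower_band_raises_inv_fwhm(self):
        wide = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=synth.default_bands(ha_sigma=12.0)), 3)
        narrow = synth.gen_spectrum_set(
            synth.SpectrumModel(bands=synth.default_bands(ha_sigma=8.0)), 3)
        _, s_wide, _ = raman.set_metrics(wide)
        _, s_narrow, _ = raman.set_metrics(narrow)
        get = lambda s: float(s.set_index("metric").loc["inv_fwhm", "mean"])  # noqa: E731
        assert get(s_narrow) > get(s_wide)

    def test_failed_spectra_counted_not_fatal(self):
        good = synth.gen_spectrum(synth.SpectrumModel(bands=synth.default_bands()))
        # restricted axis lacking the 1374 band -> per-spectrum error
        x = np.arange(600.0, 1300.0)
        bad = RamanSpectrum(axis=x, intensity=np.interp(x, good.axis, good.intensity))
        sset = SpectrumSet(spectra=(bad, bad), label="bad")
        per_spec, summary, n_failed = raman.set_metrics(sset)
        assert n_failed == 2
        assert (per_spec["error"] != "").all()

    def test_pipeline_fingerprint_recorded(self):
        sset = synth.gen_spectrum_set(synth.SpectrumModel(bands=synth.default_bands()), 2)
        per_spec, summary, _ = raman.set_metrics(sset)
        fp = PipelineConfig().fingerprint()
        assert per_spec.attrs["pipeline"] == fp
        assert "background_subtract>baseline" in fp
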