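"""Smoothing, centroiding, EIC construction, deconvolution, integration."""

import numpy as np
import pytest

from conftest import gaussian_chromatogram
from lcquant.errors import LcquantError, RangeError
from lcquant.ms_io import Run, Spectrum
from lcquant.preprocess import (Chromatogram, ProcessingConfig, build_eics,
                                centroid, deconvolve, integrate_area,
                                preset_config, smooth_sg)


class TestSavitzkyGolay:
    def test_constant_sequence_unchanged(self):
        out = smooth_sg([5.0] * 21, window=5, order=2)
        np.testing.assert_allclose(out, 5.0)

    def test_exact_on_polynomials_up_to_order(self):
        x = np.arange(21, dtype=float)
        y = x ** 2
        out = smooth_sg(y, window=7, order=2)
        # interior points reproduced exactly; mirrored edges may deviate
        np.testing.assert_allclose(out[3:-3], y[3:-3], atol=1e-9)

    def test_reduces_noise_rmse(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.3, x.shape)
        smoothed = smooth_sg(noisy, window=11, order=3)
        rmse = lambda y: float(np.sqrt(np.mean((y - clean) ** 2)))
        assert rmse(smoothed) < rmse(noisy)

    @pytest.mark.parametrize("window,order", [(4, 2), (7, 7), (7, 9)])
    def test_invalid_parameters(self, window, order):
        with pytest.raises(LcquantError):
            smooth_sg(np.ones(50), window, order)


def _profile_spectrum(mz, inten, rt=1.0):
    return Spectrum(rt=rt, mz_values=np.asarray(mz, float),
                    intensities=np.asarray(inten, float), mode="profile")


class TestCentroid:
    def test_triangular_bump_weighted_mean(self):
        # symmetric triangle peaking at 100.00 with summit 1000
        mz = [99.98, 99.99, 100.00, 100.01, 100.02]
        inten = [250.0, 500.0, 1000.0, 500.0, 250.0]
        out = centroid(_profile_spectrum(mz, inten), noise_level=50.0)
        assert len(out.mz_values) == 1
        assert out.mz_values[0] == pytest.approx(100.00, abs=1e-6)
        assert out.intensities[0] == pytest.approx(1000.0)

    def test_all_below_noise_gives_empty(self):
        out = centroid(_profile_spectrum([100.0, 100.01], [10.0, 20.0]),
                       noise_level=50.0)
        assert len(out.mz_values) == 0

    def test_two_bumps_with_subnoise_valley(self):
        mz = 100.0 + 0.01 * np.arange(9)
        inten = [100, 900, 100, 10, 10, 10, 100, 700, 100]
        out = centroid(_profile_spectrum(mz, inten), noise_level=50.0)
        assert len(out.mz_values) == 2
        # brute-force oracle: local maxima above noise
        above = np.asarray(inten) > 50.0
        maxima = [i for i in range(1, 8)
                  if above[i] and inten[i] > inten[i - 1]
                  and inten[i] >= inten[i + 1]]
        np.testing.assert_allclose(out.intensities,
                                   [inten[i] for i in maxima])

    def test_two_maxima_in_one_run_split_at_valley(self):
        mz = 100.0 + 0.01 * np.arange(6)
        inten = [100, 900, 300, 200, 700, 100]
        out = centroid(_profile_spectrum(mz, inten), noise_level=50.0)
        assert len(out.mz_values) == 2
        assert out.intensities == pytest.approx([900.0, 700.0])

    def test_centroid_spectrum_passes_through(self):
        spec = Spectrum(rt=1.0, mz_values=[100.0], intensities=[5.0],
                        mode="centroid")
        assert centroid(spec, noise_level=50.0) is spec


def _run_with_gaussian(target_mz, apex_rt, height, sigma=0.1, span=10.0,
                       dt=0.02, extra=()):
    """Centroid-mode run with Gaussian EIC peaks at given m/z values."""
    rts = np.arange(0.0, span, dt)
    spectra = []
    peaks = [(target_mz, apex_rt, height)] + list(extra)
    for rt in rts:
        mzs, ints = [], []
        for mz, apex, h in sorted(peaks):
            v = h * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
            mzs.append(mz)
            ints.append(v)
        spectra.append(Spectrum(rt=float(rt), mz_values=np.array(mzs),
                                intensities=np.array(ints),
                                mode="centroid"))
    return Run(spectra=spectra, run_id="synthetic")


class TestBuildEics:
    def test_single_gaussian_max_at_apex(self, no_smoothing_config):
        run = _run_with_gaussian(181.071, apex_rt=5.0, height=1000.0)
        (eic,) = build_eics(run, [181.071], no_smoothing_config)
        assert len(eic.rts) == len(run.spectra)
        assert eic.rts[np.argmax(eic.intensities)] == pytest.approx(5.0)

    def test_absent_target_gives_full_length_zeros(self, no_smoothing_config):
        run = _run_with_gaussian(181.071, apex_rt=5.0, height=1000.0)
        (eic,) = build_eics(run, [500.0], no_smoothing_config)
        assert len(eic.rts) == len(run.spectra)
        np.testing.assert_array_equal(eic.intensities, 0.0)

    def test_two_targets_do_not_cross_talk(self):
        config = ProcessingConfig(mz_tolerance=0.05)
        run = _run_with_gaussian(181.071, apex_rt=5.0, height=1000.0,
                                 extra=[(147.076, 2.0, 800.0)])
        eic_a, eic_b = build_eics(run, [181.071, 147.076], config)
        assert eic_a.rts[np.argmax(eic_a.intensities)] == pytest.approx(5.0)
        assert eic_b.rts[np.argmax(eic_b.intensities)] == pytest.approx(2.0)
        # each EIC is blind to the other peak's elution window
        assert eic_a.intensities[np.argmin(np.abs(eic_a.rts - 2.0))] \
            < 1e-6 * 800.0


class TestIntegrateArea:
    def test_unit_rectangle(self):
        rts = np.arange(0.0, 3.0, 0.001)
        y = np.where((rts >= 1.0) & (rts <= 2.0), 1.0, 0.0)
        chrom = Chromatogram(target_mz=100.0, mz_tolerance=0.1, rts=rts,
                             intensities=y)
        assert integrate_area(chrom, 1.0, 2.0) == pytest.approx(1.0,
                                                                rel=2e-3)

    def test_triangle_area(self):
        rts = np.arange(0.0, 2.0, 0.001)
        y = np.clip(100.0 * (1 - np.abs(rts - 1.0) / 0.25), 0.0, None)
        chrom = Chromatogram(target_mz=100.0, mz_tolerance=0.1, rts=rts,
                             intensities=y)
        assert integrate_area(chrom, 0.75, 1.25) == pytest.approx(25.0,
                                                                  rel=1e-2)

    def test_additive_over_adjacent_intervals(self, single_peak_chrom):
        a, b, c = 3.0, 5.1234, 7.0
        total = integrate_area(single_peak_chrom, a, c)
        split = integrate_area(single_peak_chrom, a, b) \
            + integrate_area(single_peak_chrom, b, c)
        assert split == pytest.approx(total, abs=1e-9)

    def test_out_of_span_bounds_rejected(self, single_peak_chrom):
        with pytest.raises(RangeError):
            integrate_area(single_peak_chrom, -1.0, 5.0)
        with pytest.raises(RangeError):
            integrate_area(single_peak_chrom, 5.0, 4.0)


def brute_force_minima(y):
    """Independent oracle: strict interior local minima (leftmost of
    plateaus)."""
    mins = []
    for k in range(1, len(y) - 1):
        j = k
        while j < len(y) - 1 and y[j + 1] == y[k]:
            j += 1
        if y[k] < y[k - 1] and j < len(y) - 1 and y[j + 1] > y[k]:
            if not mins or mins[-1] < k - 0:
                mins.append(k)
    return mins


class TestDeconvolve:
    def test_single_gaussian_one_peak(self, single_peak_chrom,
                                      no_smoothing_config):
        peaks = deconvolve(single_peak_chrom, no_smoothing_config)
        assert len(peaks) == 1
        assert peaks[0].apex_rt == pytest.approx(5.0, abs=0.02)
        assert peaks[0].height == pytest.approx(1000.0, rel=1e-6)

    def test_two_gaussians_split_at_valley(self, no_smoothing_config):
        chrom = gaussian_chromatogram(apexes=[4.0, 5.0],
                                      heights=[1000.0, 800.0])
        peaks = deconvolve(chrom, no_smoothing_config)
        assert len(peaks) == 2
        minima = brute_force_minima(chrom.intensities)
        valley_rts = chrom.rts[minima]
        # the shared border sits on a brute-force local minimum
        assert peaks[0].rt_end == peaks[1].rt_start
        assert any(np.isclose(peaks[0].rt_end, v) for v in valley_rts)

    def test_flat_zero_trace_gives_no_peaks(self, no_smoothing_config):
        chrom = Chromatogram(target_mz=100.0, mz_tolerance=0.1,
                             rts=np.arange(0.0, 5.0, 0.02),
                             intensities=np.zeros(250))
        assert deconvolve(chrom, no_smoothing_config) == []

    def test_shallow_valley_does_not_split(self, no_smoothing_config):
        # two heavily overlapping peaks: valley above the depth criterion
        chrom = gaussian_chromatogram(apexes=[4.0, 4.35],
                                      heights=[1000.0, 950.0], sigma=0.15)
        config = ProcessingConfig(sg_window=0, sg_order=0,
                                  min_valley_ratio=0.5)
        assert len(deconvolve(chrom, config)) == 1

    def test_min_peak_height_filters(self, no_smoothing_config):
        chrom = gaussian_chromatogram(apexes=[3.0, 7.0],
                                      heights=[1000.0, 50.0])
        config = ProcessingConfig(sg_window=0, sg_order=0,
                                  min_peak_height=100.0)
        peaks = deconvolve(chrom, config)
        assert len(peaks) == 1
        assert peaks[0].apex_rt == pytest.approx(3.0, abs=0.02)

    def test_peak_areas_do_not_exceed_total(self, no_smoothing_config):
        rng = np.random.default_rng(7)
        chrom = gaussian_chromatogram(apexes=[2.0, 4.5, 7.0],
                                      heights=[500.0, 900.0, 300.0],
                                      baseline=5.0, noise_sd=10.0, seed=3)
        peaks = deconvolve(chrom, no_smoothing_config)
        total = integrate_area(chrom, chrom.rts[0], chrom.rts[-1])
        assert sum(p.area for p in peaks) <= total + 1e-9

    def test_mirror_symmetry_of_borders(self, no_smoothing_config):
        chrom = gaussian_chromatogram(apexes=[3.0, 6.0],
                                      heights=[1000.0, 600.0])
        flipped = Chromatogram(
            target_mz=chrom.target_mz, mz_tolerance=0.1,
            rts=chrom.rts,
            intensities=chrom.intensities[::-1].copy())
        fwd = deconvolve(chrom, no_smoothing_config)
        rev = deconvolve(flipped, no_smoothing_config)
        span = chrom.rts[0] + chrom.rts[-1]
        fwd_borders = sorted(round(p.rt_start, 6) for p in fwd) \
            + sorted(round(p.rt_end, 6) for p in fwd)
        rev_borders = sorted(round(span - p.rt_end, 6) for p in rev) \
            + sorted(round(span - p.rt_start, 6) for p in rev)
        assert sorted(fwd_borders) == pytest.approx(sorted(rev_borders))

    @pytest.mark.parametrize("snr", [10, 50])
    def test_area_recovery_under_noise(self, snr):
        height, sigma = 1000.0, 0.1
        true_area = height * sigma * np.sqrt(2 * np.pi)
        chrom = gaussian_chromatogram(apexes=5.0, heights=height,
                                      sigma=sigma, noise_sd=height / snr,
                                      seed=snr)
        config = ProcessingConfig(min_peak_height=3 * height / snr)
        peaks = deconvolve(chrom, config)
        main = max(peaks, key=lambda p: p.height)
        assert main.area == pytest.approx(true_area, rel=0.10)


class TestPresets:
    def test_presets_are_pure_functions(self):
        a, b = preset_config("default"), preset_config("default")
        assert a == b

    def test_sensitivity_ordering(self):
        fast = preset_config("fast")
        default = preset_config("default")
        thorough = preset_config("thorough")
        assert fast.sg_window == 0
        assert fast.min_valley_ratio < default.min_valley_ratio \
            < thorough.min_valley_ratio

    def test_overrides_apply(self):
        cfg = preset_config("default", mz_tolerance=0.02)
        assert cfg.mz_tolerance == 0.02

    def test_unknown_preset_rejected(self):
        with pytest.raises(LcquantError):
            preset_config("ludicrous")
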