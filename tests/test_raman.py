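"""Spectral preprocessing, band measures and distribution statistics."""

import numpy as np
import pytest

from osteotrack import synthgen as sg
from osteotrack.raman import (
    Spectrum,
    band_height,
    baseline_subtract,
    compute_params,
    despike,
    linescan_summary,
    pmma_subtract,
    v1po4_fwhm,
    weighted_mean,
)


def _grid(step=1.0):
    return np.arange(800.0, 1800.0 + step / 2, step)


def _gauss(w, c, h, fwhm):
    s = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return h * np.exp(-((w - c) ** 2) / (2 * s**2))


class TestDespike:
    def test_single_huge_spike_removed(self):
        clean, _ = sg.make_raman_spectrum(seed=2, noise_sd=0.0)
        spiked, _ = sg.make_raman_spectrum(seed=2, noise_sd=0.0, spike_positions=[1150.0])
        out = despike(spiked)
        assert np.max(np.abs(out.intensities - clean.intensities)) < 0.01

    def test_adjacent_spike_pair_removed(self):
        clean, _ = sg.make_raman_spectrum(seed=2, noise_sd=0.0)
        spiked, _ = sg.make_raman_spectrum(
            seed=2, noise_sd=0.0, spike_positions=[1150.0, 1151.0]
        )
        out = despike(spiked)
        assert np.max(np.abs(out.intensities - clean.intensities)) < 0.01

    def test_spike_free_spectrum_untouched(self):
        s, _ = sg.make_raman_spectrum(seed=3)
        assert np.array_equal(despike(s).intensities, s.intensities)

    def test_too_many_spikes_rejected(self):
        w = _grid()
        y = np.zeros_like(w)
        y[::4] = 100.0  # 25% of channels
        with pytest.raises(ValueError):
            despike(Spectrum(w, y))


class TestBaseline:
    def test_pure_polynomial_removed(self):
        w = _grid()
        u = (w - w.mean()) / (np.ptp(w) / 2)
        y = 4.0 + 2.0 * u - 1.0 * u**2
        out = baseline_subtract(Spectrum(w, y))
        assert np.max(np.abs(out.intensities)) < 1e-6

    def test_band_height_preserved_over_cubic_background(self):
        w = _grid()
        u = (w - w.mean()) / (np.ptp(w) / 2)
        y = _gauss(w, 960.0, 8.0, 10.0) + 5.0 + 2.0 * u - 1.5 * u**2 + 0.8 * u**3
        out = baseline_subtract(Spectrum(w, y))
        assert band_height(out, 960.0) == pytest.approx(8.0, rel=0.02)

    def test_idempotent(self):
        s, _ = sg.make_raman_spectrum(seed=4, baseline_coeffs=(5.0, 2.0, -1.5, 0.8))
        once = baseline_subtract(s)
        twice = baseline_subtract(once)
        scale = np.max(np.abs(once.intensities))
        assert np.max(np.abs(twice.intensities - once.intensities)) < 0.005 * scale


class TestPmmaSubtract:
    def test_known_mixture_coefficient(self, pmma_ref):
        w = _grid()
        bone = _gauss(w, 960.0, 8.0, 10.0) + _gauss(w, 1670.0, 1.0, 14.0)
        mix = bone + 0.4 * np.interp(w, pmma_ref.wavenumbers, pmma_ref.intensities)
        out, alpha = pmma_subtract(Spectrum(w, mix), pmma_ref)
        assert alpha == pytest.approx(0.4, rel=0.02)
        assert band_height(out, 812.0) < 0.02

    def test_no_resin_leaves_spectrum_unchanged(self, pmma_ref):
        w = _grid()
        bone = _gauss(w, 960.0, 8.0, 10.0)
        out, alpha = pmma_subtract(Spectrum(w, bone), pmma_ref)
        assert alpha == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(out.intensities, bone, atol=1e-6)


class TestBandMeasures:
    def test_single_gaussian_height(self):
        w = _grid()
        s = Spectrum(w, _gauss(w, 960.0, 8.0, 10.0))
        assert band_height(s, 960.0) == pytest.approx(8.0, rel=0.01)
        assert band_height(s, 960.0, method="max") == pytest.approx(8.0, rel=0.01)

    def test_flat_zero_is_zero(self):
        s = Spectrum(_grid(), np.zeros_like(_grid()))
        assert band_height(s, 1070.0) == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_grid_rejected(self):
        s = Spectrum(_grid(), np.zeros_like(_grid()))
        with pytest.raises(ValueError):
            band_height(s, 805.0)

    def test_fwhm_of_known_gaussian(self):
        w = _grid()
        sigma = 4.0
        s = Spectrum(w, 8.0 * np.exp(-((w - 960.0) ** 2) / (2 * sigma**2)))
        expect = 2 * np.sqrt(2 * np.log(2)) * sigma  # 9.42 cm^-1
        assert v1po4_fwhm(s) == pytest.approx(expect, rel=0.02)
        assert 1.0 / v1po4_fwhm(s) == pytest.approx(0.1062, rel=0.02)

    def test_doubling_width_halves_crystallinity(self):
        w = _grid()
        s1 = Spectrum(w, _gauss(w, 960.0, 8.0, 10.0))
        s2 = Spectrum(w, _gauss(w, 960.0, 8.0, 20.0))
        assert v1po4_fwhm(s2) == pytest.approx(2 * v1po4_fwhm(s1), rel=0.02)

    def test_fwhm_grid_refinement(self):
        for step in (1.0, 0.5):
            w = _grid(step)
            s = Spectrum(w, _gauss(w, 960.0, 8.0, 9.42))
            assert v1po4_fwhm(s) == pytest.approx(9.42, rel=0.02)


class TestComputeParams:
    def test_construction_ratios(self, pmma_ref):
        s, truth = sg.make_raman_spectrum(
            {960.0: 8.0, 1670.0: 1.0, 1070.0: 1.3}, pmma_scale=0.5, noise_sd=0.0, seed=0
        )
        p = compute_params(s, pmma_ref)
        assert p.mmr == pytest.approx(8.0, rel=0.02)
        assert p.carb_phos == pytest.approx(1.3 / 8.0, rel=0.02)

    def test_scale_invariance(self, pmma_ref):
        s, _ = sg.random_spectrum(6)
        p1 = compute_params(s, pmma_ref)
        p5 = compute_params(s.with_intensities(5.0 * s.intensities), pmma_ref)
        for k, v in p1.as_dict().items():
            assert getattr(p5, k) == pytest.approx(v, rel=0.02), k

    def test_no_resin_gives_near_zero_nanoporosity(self, pmma_ref):
        s, _ = sg.make_raman_spectrum(pmma_scale=0.0, seed=1)
        p = compute_params(s, pmma_ref)
        assert p.nanoporosity < 0.01

    def test_nanoporosity_precedes_subtraction(self, pmma_ref):
        """Computing the resin/phosphate ratio after subtraction would erase
        it; the pipeline must measure it on the pre-subtraction spectrum."""
        s, truth = sg.random_spectrum(3)
        p = compute_params(s, pmma_ref)
        assert p.nanoporosity == pytest.approx(truth.nanoporosity, rel=0.06)
        sb = baseline_subtract(despike(s))
        post, _ = pmma_subtract(sb, pmma_ref)
        nano_post = band_height(post, 812.0) / band_height(post, 960.0)
        assert nano_post < 0.5 * p.nanoporosity


class TestLinescanSummary:
    def test_normal_sample_summary(self):
        vals = np.random.default_rng(0).normal(11.0, 1.0, 500)
        s = linescan_summary(vals)
        assert s.mean == pytest.approx(11.0, abs=0.15)
        assert s.fwhm == pytest.approx(2.355, abs=0.3)
        assert s.n_points == 500

    def test_median_sampling_behaviour(self):
        """Median over replicates of the N(11,1) n=500 experiment."""
        r2s, fwhms, means = [], [], []
        for k in range(11):
            vals = np.random.default_rng(1000 + k).normal(11.0, 1.0, 500)
            s = linescan_summary(vals)
            r2s.append(s.r2_gaussian)
            fwhms.append(s.fwhm)
            means.append(s.mean)
        assert np.median(r2s) > 0.95
        assert np.median(means) == pytest.approx(11.0, abs=0.15)
        assert np.median(fwhms) == pytest.approx(2.355, abs=0.3)

    def test_hand_histogram_weighted_mean(self):
        assert weighted_mean([1.0, 2.0, 3.0], [20.0, 60.0, 20.0]) == pytest.approx(2.0)

    def test_mean_close_to_arithmetic_mean(self, rng):
        vals = rng.gamma(5.0, 1.0, 400)
        s = linescan_summary(vals)
        bin_w = s.bin_edges[1] - s.bin_edges[0]
        assert abs(s.mean - vals.mean()) <= 0.5 * bin_w + 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linescan_summary(np.full(100, 3.0))
        with pytest.raises(ValueError):
            linescan_summary(np.arange(10.0))
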