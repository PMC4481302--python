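"""Spectral estimation, band power, preprocessing, correlation, maps."""

import numpy as np
import pytest

from cortexlfp.analysis import (
    band_peak,
    band_peak_excess,
    crosscorr_map,
    gamma_power,
    gamma_power_map,
    lfp_magnitude,
    lfp_range,
    multitaper_psd,
    preprocess_recordings,
)


class TestMagnitude:
    def test_unit_sinusoid(self):
        t = np.arange(100_000) / 1000.0
        assert lfp_magnitude(np.sin(2 * np.pi * 7 * t)) == pytest.approx(
            1 / np.sqrt(2), rel=1e-3)

    def test_constant_signal_is_zero(self):
        assert lfp_magnitude(np.full(100, 3.3)) == 0.0

    def test_white_noise_recovers_sigma(self):
        x = np.random.default_rng(0).normal(0, 3.0, 100_000)
        assert lfp_magnitude(x) == pytest.approx(3.0, abs=0.05)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lfp_magnitude([1.0])


class TestRange:
    def test_constant_curve_crosses_immediately(self):
        r = np.linspace(0, 1000, 21)
        assert lfp_range(r, np.full(21, 2.0)) == 0.0

    def test_linear_curve(self):
        r = np.linspace(0, 1000, 101)
        assert lfp_range(r, r / 1000.0) == pytest.approx(950.0, rel=1e-6)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        r = np.linspace(0, 1000, 41)
        m = np.cumsum(rng.random(41))        # monotone increasing
        got = lfp_range(r, m)
        target = 0.95 * m[-1]
        fine = np.linspace(0, 1000, 200_001)
        interp = np.interp(fine, r, m)
        brute = fine[np.argmax(interp >= target)]
        assert got == pytest.approx(brute, abs=0.01)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lfp_range([0, 1, 2], [1.0, np.nan, 2.0])


class TestMultitaper:
    def test_peak_at_sinusoid_frequency(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 40 * t) + 0.01 * np.random.default_rng(0).normal(size=2000)
        est = multitaper_psd(x, fs, 3.0)
        assert est.frequencies[np.argmax(est.power)] == pytest.approx(40.0, abs=1.0)

    @pytest.mark.parametrize("nw, k", [(3.0, 5), (10.0, 19)])
    def test_taper_count_is_2nw_minus_1(self, nw, k):
        est = multitaper_psd(np.random.default_rng(1).normal(size=4000), 1000.0, nw)
        assert est.n_tapers == k

    def test_confidence_band_contains_estimate(self):
        est = multitaper_psd(np.random.default_rng(2).normal(size=1000), 1000.0, 3.0)
        assert np.all(est.ci_lower <= est.power)
        assert np.all(est.power <= est.ci_upper)

    def test_white_noise_ci_coverage(self):
        """Pointwise 95% chi-squared band covers the true flat density."""
        fs, n, reps = 1000.0, 512, 500
        rng = np.random.default_rng(3)
        true_psd = 2.0 / fs  # one-sided density of unit-variance white noise
        hits = 0
        total = 0
        for _ in range(reps):
            est = multitaper_psd(rng.normal(size=n), fs, 3.0)
            sel = slice(5, len(est.frequencies) - 5)
            hits += np.sum((est.ci_lower[sel] <= true_psd)
                           & (true_psd <= est.ci_upper[sel]))
            total += est.power[sel].size
        assert hits / total == pytest.approx(0.95, abs=0.02)

    def test_parseval_total_power(self):
        x = np.random.default_rng(4).normal(size=8192)
        est = multitaper_psd(x, 1000.0, 3.0)
        total = np.trapezoid(est.power, est.frequencies)
        assert total == pytest.approx(np.var(x), rel=0.1)

    def test_normalized_spectrum_has_unit_power(self):
        est = multitaper_psd(np.random.default_rng(5).normal(size=1000),
                             1000.0, 3.0, normalize=True)
        assert np.trapezoid(est.power, est.frequencies) == pytest.approx(1.0)

    def test_low_time_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            multitaper_psd(np.zeros(100), 1000.0, 0.5)


class TestGammaPower:
    def test_flat_unit_density_gives_band_width(self):
        f = np.linspace(0, 500, 2001)
        assert gamma_power(f, np.ones_like(f), (20, 40)) == pytest.approx(20.0)

    def test_narrow_peak_recovers_area(self):
        f = np.linspace(0, 100, 10_001)
        p = np.zeros_like(f)
        sel = (f > 29.5) & (f < 30.5)
        p[sel] = 7.0  # area = 7
        assert gamma_power(f, p, (20, 40)) == pytest.approx(7.0, rel=0.01)

    def test_matches_fine_riemann_sum(self):
        rng = np.random.default_rng(6)
        f = np.linspace(0, 200, 4001)
        p = np.abs(np.cumsum(rng.normal(size=4001)))
        got = gamma_power(f, p, (20, 40))
        fine = np.linspace(20, 40, 2_000_001)
        brute = np.sum(np.interp(fine, f, p)) * (fine[1] - fine[0])
        assert got == pytest.approx(brute, rel=1e-3)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            gamma_power(np.linspace(0, 30, 31), np.ones(31), (20, 40))


class TestPeakDetection:
    def _spectrum(self, osc_amp):
        fs = 1000.0
        rng = np.random.default_rng(7)
        t = np.arange(1500) / fs
        # pink-ish noise plus an optional 40-Hz oscillation
        noise = np.cumsum(rng.normal(size=1500)) * 0.05 + rng.normal(size=1500)
        x = noise + osc_amp * np.sin(2 * np.pi * 40 * t)
        return multitaper_psd(x, fs, 3.0)

    def test_oscillation_scores_high_excess(self):
        est = self._spectrum(2.0)
        f, ex = band_peak_excess(est.frequencies, est.power)
        assert ex > 1.0
        assert f == pytest.approx(40.0, abs=5.0)

    def test_featureless_spectrum_scores_low(self):
        est = self._spectrum(0.0)
        _, ex = band_peak_excess(est.frequencies, est.power)
        assert ex < 0.5

    def test_prominence_variant_agrees(self):
        est = self._spectrum(2.0)
        f, pr = band_peak(est.frequencies, est.power)
        assert pr > 0.5 and f == pytest.approx(40.0, abs=5.0)


class TestPopulationSweepVariants:
    def test_empty_population_gives_zero_lfp(self):
        from cortexlfp.analysis import run_population_sweep
        res = run_population_sweep("l23_pyramid", n_neurons=0, duration=100.0,
                                   discard=0.0, seed=0)
        assert np.all(res.magnitudes == 0)

    def test_correlated_perisomatic_input_amplifies_the_lfp(self):
        """Pooled trains at the soma make the neurons' dipoles coherent, so
        the population LFP magnitude grows strongly relative to independent
        drive at the same placement."""
        from cortexlfp.analysis import run_population_sweep
        common = dict(n_neurons=120, n_synapses=100, duration=500.0,
                      discard=100.0, seed=3, input_mode="soma")
        indep = run_population_sweep("l23_pyramid", **common)
        pooled = run_population_sweep("l23_pyramid", pool_size=120, **common)
        # the amplification is strongest away from the soma plane, where the
        # coherent dipolar far fields add; at the soma plane the nearest
        # neurons dominate regardless of correlation
        off_soma = 0  # deepest electrode, -300 um
        assert pooled.magnitudes[off_soma, -1] > 3.0 * indep.magnitudes[off_soma, -1]
        assert pooled.soma_magnitude > indep.soma_magnitude

    def test_soma_targeted_input_and_depth_jitter_run(self):
        from cortexlfp.analysis import run_population_sweep
        res = run_population_sweep("l23_pyramid", n_neurons=50, n_synapses=100,
                                   input_mode="soma", duration=300.0,
                                   discard=50.0, soma_depth_range=(-100.0, 100.0),
                                   seed=4)
        assert np.all(np.isfinite(res.magnitudes))
        assert res.magnitudes[res.soma_depth_index, -1] > 0

    def test_radius_grid_outside_cylinder_rejected(self):
        from cortexlfp.analysis import run_population_sweep
        with pytest.raises(ValueError, match="radius grid"):
            run_population_sweep("l23_pyramid", n_neurons=5,
                                 radius_grid=np.array([0.0, 2000.0]))


class TestPreprocessing:
    def test_identical_channels_car_to_zero(self):
        """CAR cancels a component common to all channels exactly."""
        rng = np.random.default_rng(8)
        common = rng.normal(size=4000)
        # purely identical channels are zeroed by CAR, which the final
        # z-normalisation then reports as degenerate
        with pytest.raises(ValueError, match="zero-variance"):
            preprocess_recordings(np.tile(common, (4, 1)), 1000.0,
                                  experimental=True)
        # with distinct residuals on top, the common part is removed: the
        # two outputs are exact mirror images
        resid = rng.normal(size=4000)
        x = np.vstack([common + resid, common - resid])
        out = preprocess_recordings(x, 1000.0, experimental=True)
        np.testing.assert_allclose(out[0], -out[1], atol=1e-9)

    def test_line_noise_attenuated_by_20_db(self):
        fs = 1000.0
        t = np.arange(10_000) / fs
        clean = np.sin(2 * np.pi * 23 * t)
        x = np.vstack([clean + np.sin(2 * np.pi * 50 * t),
                       -clean + np.sin(2 * np.pi * 50 * t)])
        out = preprocess_recordings(x, fs, experimental=True)
        # project onto the 50-Hz quadrature pair to measure residual amplitude
        c = np.cos(2 * np.pi * 50 * t)
        s = np.sin(2 * np.pi * 50 * t)
        resid = np.hypot(out[0] @ c, out[0] @ s) / (len(t) / 2)
        # input amplitude 1 (in normalised units ~1/std); require >= 20 dB down
        assert resid < 0.1 * np.abs(out[0] @ np.sin(2 * np.pi * 23 * t)
                                    ) / (len(t) / 2) + 0.05

    def test_passband_amplitude_preserved(self):
        fs = 10_000.0
        t = np.arange(int(fs * 10)) / fs
        x = np.sin(2 * np.pi * 30 * t)[None, :]
        out = preprocess_recordings(x, fs, experimental=False)
        tt = np.arange(out.shape[1]) / 1000.0
        amp = 2 * np.abs(out[0] @ np.exp(-2j * np.pi * 30 * tt)) / out.shape[1]
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_resampling_to_1khz(self):
        x = np.random.default_rng(9).normal(size=(2, 20_000))
        out = preprocess_recordings(x, 10_000.0, experimental=False)
        assert out.shape[1] == 2000

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="band edge"):
            preprocess_recordings(np.zeros((2, 1000)), 500.0)

    def test_experimental_output_is_z_normalised(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(3, 8000)) * np.array([[1.0], [5.0], [0.2]])
        out = preprocess_recordings(x, 1000.0, experimental=True)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1), 1.0, rtol=1e-9)


class TestCrossCorrelation:
    def test_reference_autocorrelation_peaks_at_one(self):
        x = np.random.default_rng(11).normal(size=(3, 2000))
        lags, cc = crosscorr_map(x, reference=1)
        zero = np.flatnonzero(lags == 0)[0]
        assert cc[1, zero] == pytest.approx(1.0, abs=1e-9)

    def test_sign_inverted_channel_gives_minus_one(self):
        ref = np.random.default_rng(12).normal(size=2000)
        lags, cc = crosscorr_map(np.vstack([ref, -ref]), reference=0)
        zero = np.flatnonzero(lags == 0)[0]
        assert cc[1, zero] == pytest.approx(-1.0, abs=1e-9)

    def test_antiphase_sinusoids(self):
        t = np.arange(4000) / 1000.0
        period = 50  # samples at 20 Hz
        a = np.sin(2 * np.pi * 20 * t)
        b = np.sin(2 * np.pi * 20 * t + np.pi)
        lags, cc = crosscorr_map(np.vstack([a, b]), reference=0, max_lag=60)
        zero = np.flatnonzero(lags == 0)[0]
        assert cc[1, zero] < -0.9
        half = np.flatnonzero(lags == period // 2)[0]
        assert cc[1, half] > 0.85

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(ValueError):
            crosscorr_map(np.vstack([np.ones(100), np.random.default_rng(0).normal(size=100)]),
                          reference=0)


class TestGammaMap:
    def test_uniform_powers_give_uniform_map(self):
        out = gamma_power_map(np.full((5, 5), 2.5), upsample=4)
        np.testing.assert_allclose(out, 2.5, rtol=1e-9)

    def test_interpolant_reproduces_node_values(self):
        rng = np.random.default_rng(13)
        p = rng.random((6, 6))
        up = 10
        out = gamma_power_map(p, upsample=up)
        np.testing.assert_allclose(out[::up, ::up], p, atol=1e-9)

    def test_single_hot_electrode_bump(self):
        p = np.zeros((7, 7))
        p[3, 3] = 1.0
        out = gamma_power_map(p, upsample=10)
        peak = np.unravel_index(np.nanargmax(out), out.shape)
        assert abs(peak[0] - 35) <= 5 and abs(peak[1] - 35) <= 5
        # decays away from the bump
        assert out[5, 5] < out[30, 30]

    def test_small_grid_falls_back_to_bilinear(self):
        with pytest.warns(UserWarning, match="bilinear"):
            out = gamma_power_map(np.ones((3, 3)), upsample=3)
        np.testing.assert_allclose(out, 1.0)

    def test_mask_propagates_as_nan(self):
        p = np.ones((6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0] = True
        out = gamma_power_map(p, upsample=5, mask=mask)
        assert np.isnan(out[0, 0])
        assert np.isfinite(out[-1, -1])
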