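"""Signal analyses: filtering, envelopes, cycle statistics, FC, spectra."""

import numpy as np
import pytest

from hybridbnm import analysis
from hybridbnm.hemodynamics import BOLDSeries


def sine(freq, duration, rate=1000.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return np.sin(2 * np.pi * freq * t + phase)


def spectral_noise(slope, n, rate=1.0, seed=0):
    """Gaussian noise shaped so its PSD follows f**slope."""
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    amp = np.zeros(len(freqs))
    amp[1:] = freqs[1:] ** (slope / 2.0)
    return np.fft.irfft(spec * amp, n=n)


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        x = sine(10.0, 60.0)
        y = analysis.bandpass(x, 8.0, 12.0)
        mid = slice(10000, 50000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_out_of_band_rejected(self):
        x = sine(1.0, 60.0)
        y = analysis.bandpass(x, 8.0, 12.0)
        assert np.abs(y[10000:50000]).max() < 0.01

    def test_invalid_band(self):
        with pytest.raises(ValueError, match="band"):
            analysis.bandpass(np.zeros(1000), 8.0, 600.0)


class TestAlphaPowerEnvelope:
    def test_flat_for_constant_amplitude(self):
        x = sine(9.0, 200.0)
        env = analysis.alpha_power_envelope(x)
        assert env.std() / env.mean() < 0.01

    def test_recovers_am_envelope(self):
        t = np.arange(300000) / 1000.0
        programmed = 1.0 + 0.5 * np.sin(2 * np.pi * 0.02 * t)
        x = programmed * np.sin(2 * np.pi * 9.0 * t)
        env = analysis.alpha_power_envelope(x, band=(8.0, 10.0))
        cut = (len(t) - len(env)) // 2
        r = np.corrcoef(env, programmed[cut:cut + len(env)])[0, 1]
        assert r > 0.99

    def test_trim_span(self):
        x = sine(9.0, 200.0)
        env = analysis.alpha_power_envelope(x, trim=50.0)
        assert len(env) == 200000 - 2 * 50000

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            analysis.alpha_power_envelope(sine(9.0, 60.0))


class TestAlphaRegressor:
    def test_shift_search_has_seven_candidates(self):
        """Shifts -3..+3 scans are searched; the winning shift is one of
        exactly seven candidates."""
        rng = np.random.default_rng(0)
        env = 1 + 0.3 * np.abs(sine(0.02, 400.0))
        fmri = rng.standard_normal((3, 180))
        _, shift, _ = analysis.alpha_regressor(env, 1.94, 180, fmri,
                                               offset_scans=10)
        assert -3 <= shift <= 3

    def test_matches_brute_force_convolution(self):
        env = 1 + 0.5 * np.abs(sine(0.01, 300.0))
        hrf = analysis.canonical_hrf(1000.0)
        direct = np.convolve(env, hrf)[:len(env)][::1940]
        fmri = -direct[10:10 + 130][None, :]
        reg, shift, r = analysis.alpha_regressor(env, 1.94, 130, fmri,
                                                 offset_scans=10)
        assert shift == 0
        assert r == pytest.approx(-1.0)
        assert reg == pytest.approx(direct[10:140])

    def test_constant_envelope_degenerate(self):
        with pytest.raises(ValueError, match="constant envelope"):
            analysis.alpha_regressor(np.zeros(100000), 1.94, 40,
                                     np.random.default_rng(0).standard_normal((2, 40)))


class TestCycleDetection:
    def test_pure_sine_all_cycles_accepted(self):
        x = sine(10.0, 60.0)
        cycles = analysis.detect_cycles(x)
        # one cycle per 100 ms, minus edge cycles; crossing quantization
        # may jitter lengths by one sample
        assert len(cycles) == pytest.approx(599, abs=2)
        assert all(99 <= b - a <= 101 for a, b in cycles)

    def test_jittered_cycles_match_census(self):
        """Acceptance count equals a brute-force census of zero-crossing
        intervals inside the window."""
        rng = np.random.default_rng(1)
        # frequency-wobbled sine: cycle lengths vary around 100 ms
        t = np.arange(60000) / 1000.0
        freq = 10.0 + 0.8 * np.sin(2 * np.pi * 0.2 * t)
        phase = 2 * np.pi * np.cumsum(freq) / 1000.0
        x = np.sin(phase)
        cycles = analysis.detect_cycles(x)
        rising = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1
        expected = sum(1 for a, b in zip(rising[:-1], rising[1:])
                       if 95 <= b - a <= 105)
        assert len(cycles) == expected
        assert all(95 <= b - a <= 105 for a, b in cycles)

    def test_grand_average_of_sine_is_one_cycle(self):
        x = sine(10.0, 60.0)
        waves = analysis.cycle_locked_average({"ref": x}, x)
        grid = np.linspace(0, 1, waves.n_points)
        expected = np.sin(2 * np.pi * grid)
        assert np.abs(waves.waveforms["ref"] - expected).max() < 0.05

    def test_no_cycles_raises(self):
        with pytest.raises(ValueError, match="no cycles"):
            analysis.cycle_locked_average({"x": np.ones(1000)},
                                          np.ones(1000))


class TestPhaseBinFiring:
    def test_constant_rate_normalizes_to_one(self):
        ref = sine(10.0, 30.0)
        hist = analysis.phase_bin_firing(np.full(len(ref), 5.0), ref)
        assert hist == pytest.approx(np.ones(6), abs=1e-12)

    def test_inverted_sine_matches_analytic_segment_means(self):
        """Rate = 1 - 0.5*sin(phase): per-segment means follow the
        closed-form integrals of the sine over each sixth of the cycle."""
        ref = sine(10.0, 60.0)
        rate = 1.0 - 0.5 * ref
        hist = analysis.phase_bin_firing(rate, ref)
        edges = np.linspace(0, 2 * np.pi, 7)
        seg = np.array([
            1.0 - 0.5 * (np.cos(a) - np.cos(b)) / (b - a)
            for a, b in zip(edges[:-1], edges[1:])
        ])
        assert hist == pytest.approx(seg, abs=0.01)

    def test_zero_rate_cycles_skipped(self):
        ref = sine(10.0, 2.0)
        with pytest.raises(ValueError, match="zero mean rate"):
            analysis.phase_bin_firing(np.zeros(len(ref)), ref)


class TestFunctionalConnectivity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(2)
        fc = analysis.functional_connectivity(rng.standard_normal((5, 200)))
        assert analysis.fc_similarity(fc, fc) == pytest.approx(1.0)

    def test_white_noise_fc_near_zero(self):
        rng = np.random.default_rng(3)
        fc = analysis.functional_connectivity(rng.standard_normal((6, 600)))
        off = np.abs(fc[np.tril_indices(6, -1)])
        assert off.mean() < 0.1

    def test_identical_series_correlate_fully(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        v = np.vstack([x, x, rng.standard_normal(100)])
        fc = analysis.functional_connectivity(v)
        assert fc[0, 1] == pytest.approx(1.0)

    def test_constant_region_flagged_nan(self):
        v = np.vstack([np.ones(50), np.random.default_rng(5).standard_normal(50)])
        fc = analysis.functional_connectivity(v)
        assert np.isnan(fc[0, 1])
        assert fc[0, 0] == 1.0

    def test_sliding_window_count(self):
        rng = np.random.default_rng(6)
        bold = BOLDSeries(rng.standard_normal((4, 130)))
        fcs = analysis.sliding_window_fc(bold, window=100, step=1)
        assert len(fcs) == 130 - 100 + 1

    def test_sliding_window_stationary_noise(self):
        """Window-wise FC stays close to the static FC for stationary
        input with a heterogeneous correlation structure."""
        rng = np.random.default_rng(7)
        shared = rng.standard_normal(1200)
        gains = np.linspace(0.3, 1.5, 10)
        v = np.vstack([g * shared + rng.standard_normal(1200)
                       for g in gains])
        static = analysis.functional_connectivity(v)
        sims = [analysis.fc_similarity(w, static)
                for w in analysis.sliding_window_fc(v, window=400, step=200)]
        assert min(sims) > 0.8


class TestPredictionQuality:
    def test_identity_and_sign(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 120))
        assert analysis.prediction_quality(x, x) == pytest.approx(1.0)
        assert analysis.prediction_quality(x, -x) == pytest.approx(-1.0)

    def test_snr_attenuation(self):
        """Adding noise at known SNR attenuates r to 1/sqrt(1 + 1/SNR)."""
        rng = np.random.default_rng(9)
        snr = 4.0
        x = rng.standard_normal((30, 4000))
        noisy = x + rng.standard_normal(x.shape) / np.sqrt(snr)
        expected = 1.0 / np.sqrt(1.0 + 1.0 / snr)
        assert analysis.prediction_quality(noisy, x) == pytest.approx(
            expected, abs=0.02)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            analysis.prediction_quality(np.zeros((2, 10)), np.zeros((3, 10)))


class TestWelchPowerlaw:
    def test_white_noise_flat(self):
        rng = np.random.default_rng(10)
        fit = analysis.welch_powerlaw(rng.standard_normal(20000),
                                      sample_rate=2.0)
        assert abs(fit.beta) < 0.1

    @pytest.mark.parametrize("slope", [-0.8, -0.5])
    def test_recovers_synthesized_slope(self, slope):
        x = spectral_noise(slope, 2 ** 16, rate=2.0, seed=11)
        fit = analysis.welch_powerlaw(x, sample_rate=2.0)
        assert fit.beta == pytest.approx(slope, abs=0.05)

    def test_psd_normalized(self):
        rng = np.random.default_rng(12)
        fit = analysis.welch_powerlaw(rng.standard_normal(20000),
                                      sample_rate=2.0)
        df = fit.freqs[1] - fit.freqs[0]
        # the stored band is a slice of a unit-integral spectrum
        assert np.trapezoid(fit.psd, dx=df) < 1.0 + 1e-6

    def test_band_unresolvable(self):
        with pytest.raises(ValueError, match="too short"):
            analysis.welch_powerlaw(np.zeros(100), sample_rate=1.0)


class TestDFA:
    def test_white_noise_exponent_half(self):
        rng = np.random.default_rng(13)
        v = analysis.dfa_scalefree_test(rng.standard_normal(2 ** 14))
        assert v.dfa_exponent == pytest.approx(0.5, abs=0.1)
        assert v.is_scale_free

    def test_recovers_persistent_noise_exponent(self):
        """Noise with PSD ~ f^-0.6 has DFA exponent (1+0.6)/2 = 0.8."""
        x = spectral_noise(-0.6, 2 ** 15, seed=14)
        v = analysis.dfa_scalefree_test(x)
        assert v.dfa_exponent == pytest.approx(0.8, abs=0.1)

    def test_periodic_signal_not_scale_free(self):
        rng = np.random.default_rng(15)
        t = np.arange(2 ** 14)
        x = np.sin(2 * np.pi * 0.01 * t) + 0.05 * rng.standard_normal(len(t))
        v = analysis.dfa_scalefree_test(x)
        assert not v.is_scale_free

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            analysis.dfa_scalefree_test(np.zeros(100))


class TestMovingAverage:
    def test_constant_unchanged(self):
        x = np.full(500, 2.5)
        assert analysis.moving_average_rate(x, 100.0) == pytest.approx(x)

    def test_window_one_sample_identity(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(300)
        out = analysis.moving_average_rate(x, 1.0)
        assert np.array_equal(out, x)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(400)
        w = 25
        out = analysis.moving_average_rate(x, float(w))
        brute = np.array([
            x[max(i - (w - 1) // 2, 0):min(i + w // 2 + 1, len(x))].mean()
            for i in range(len(x))
        ])
        assert out == pytest.approx(brute)
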