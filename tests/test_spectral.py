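"""PSD analytics, Morlet decomposition and the evoked/induced split."""

import numpy as np
import pytest

from fxs_oscillo import (
    BandSpec,
    EffectConfig,
    EmptyInputError,
    Session,
    SubjectMeta,
    UndefinedValueError,
    ValidationError,
    band_power,
    baseline_psd,
    evoked_induced_gamma,
    generate_recording,
    relative_gamma,
    tf_decompose,
)
from fxs_oscillo.preprocess import extract_epochs
from fxs_oscillo.spectral import morlet_grid, morlet_power
from fxs_oscillo.synth import gabor, pink_noise
from helpers import make_epochs, make_recording, sine_recording


class TestBaselinePsd:
    def test_sine_power_is_half_amplitude_squared(self):
        rec = sine_recording(freq=40.0, amp=10.0, dur=10.0)
        freqs, psd = baseline_psd(rec, baseline_span_s=10.0)
        total = band_power(freqs, psd, (1.0, 500.0))
        assert total == pytest.approx(50.0, rel=0.02)

    def test_zero_signal_zero_spectrum(self):
        rec = make_recording(np.zeros(20_000), fs=2000.0)
        _, psd = baseline_psd(rec, baseline_span_s=10.0)
        assert np.all(psd == 0.0)

    def test_white_noise_satisfies_parseval(self, rng):
        sigma = 3.0
        x = rng.normal(0, sigma, size=120_000)
        rec = make_recording(x, fs=2000.0)
        freqs, psd = baseline_psd(rec, baseline_span_s=60.0)
        assert band_power(freqs, psd, (0.0, 1000.0)) == pytest.approx(
            sigma ** 2, rel=0.10)

    def test_missing_span_is_an_error(self):
        rec = make_recording(np.zeros(1000), fs=1000.0, events=[0.5])
        with pytest.raises(ValidationError, match="baseline"):
            baseline_psd(rec, baseline_span_s=10.0)


class TestBandPower:
    def test_sine_power_lands_in_gamma_not_beta(self):
        rec = sine_recording(freq=40.0, amp=10.0, dur=10.0)
        freqs, psd = baseline_psd(rec, baseline_span_s=10.0)
        assert band_power(freqs, psd, (30.0, 80.0)) == pytest.approx(50.0, rel=0.02)
        assert band_power(freqs, psd, (13.0, 30.0)) <= 0.5

    def test_flat_psd_rectangle_rule(self):
        freqs = np.arange(0.0, 151.0)
        psd = np.where(freqs >= 1.0, 2.0, 0.0)
        assert band_power(freqs, psd, (30.0, 80.0)) == pytest.approx(100.0)

    def test_partition_additivity_is_exact(self, rng):
        freqs = np.arange(0.0, 200.0, 0.5)
        psd = rng.random(freqs.size)
        parts = [(1.0, 30.0), (30.0, 80.0), (80.0, 120.0)]
        total = band_power(freqs, psd, (1.0, 120.0))
        assert sum(band_power(freqs, psd, b) for b in parts) == pytest.approx(
            total, rel=1e-12)

    def test_empty_or_unsupported_band_rejected(self):
        freqs = np.arange(0.0, 100.0)
        psd = np.ones_like(freqs)
        with pytest.raises(ValidationError):
            band_power(freqs, psd, (50.0, 50.0))
        with pytest.raises(ValidationError):
            band_power(freqs, psd, (50.0, 150.0))


class TestRelativeGamma:
    def test_pure_gamma_sine_close_to_one(self):
        rec = sine_recording(freq=40.0, amp=10.0, dur=10.0)
        freqs, psd = baseline_psd(rec, baseline_span_s=10.0)
        assert relative_gamma(freqs, psd) >= 0.99

    def test_pure_alpha_sine_close_to_zero(self):
        rec = sine_recording(freq=10.0, amp=10.0, dur=10.0)
        freqs, psd = baseline_psd(rec, baseline_span_s=10.0)
        assert relative_gamma(freqs, psd) <= 0.01

    def test_flat_spectrum_gives_bandwidth_ratio(self):
        freqs = np.arange(0.0, 150.0)
        psd = np.where(freqs >= 1.0, 1.0, 0.0)
        assert relative_gamma(freqs, psd) == pytest.approx(50.0 / 119.0, rel=1e-9)

    def test_zero_power_is_undefined(self):
        freqs = np.arange(0.0, 150.0)
        with pytest.raises(UndefinedValueError):
            relative_gamma(freqs, np.zeros_like(freqs))


class TestMorlet:
    def test_pure_sine_ridge_at_its_frequency(self):
        fs = 1000.0
        t = np.arange(int(3 * fs)) / fs
        freqs, power = tf_decompose(np.sin(2 * np.pi * 45.0 * t), fs)
        mid = power[:, power.shape[1] // 2]
        assert abs(freqs[np.argmax(mid)] - 45.0) <= 1.0

    def test_power_scales_quadratically(self, rng):
        fs = 1000.0
        x = rng.normal(size=3000)
        _, p1 = tf_decompose(x, fs)
        _, p3 = tf_decompose(3.0 * x, fs)
        np.testing.assert_allclose(p3, 9.0 * p1, rtol=1e-9)

    def test_burst_localized_in_time_and_frequency(self):
        fs = 1000.0
        t = np.arange(int(3 * fs)) / fs
        x = gabor(t, 1.5, 0.05, 40.0, 5.0)
        freqs, power = tf_decompose(x, fs)
        fi, ti = np.unravel_index(np.argmax(power), power.shape)
        assert abs(freqs[fi] - 40.0) <= 1.0
        assert abs(t[ti] - 1.5) <= 0.02

    def test_frequencies_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            tf_decompose(np.zeros(4000), fs=200.0)  # grid extends to 120 Hz

    def test_signal_shorter_than_wavelet_rejected(self):
        with pytest.raises(ValidationError, match="wavelet"):
            tf_decompose(np.zeros(300), fs=1000.0)

    def test_matches_mne_morlet_up_to_normalization(self, rng):
        # independent implementation check: per-frequency ratio against
        # MNE's Morlet TFR must be constant over time
        mne = pytest.importorskip("mne")
        fs = 500.0
        x = rng.normal(size=2000)
        freqs = np.arange(20.0, 81.0, 5.0)
        cycles = np.linspace(4.0, 8.0, freqs.size)
        mine = morlet_power(x, fs, freqs, cycles)[:, 0, :]
        theirs = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], fs, freqs, n_cycles=cycles, output="power",
            zero_mean=False, verbose="error")[0, 0]
        sl = slice(200, 1800)  # avoid edge effects
        ratio = mine[:, sl] / theirs[:, sl]
        cv = ratio.std(axis=1) / ratio.mean(axis=1)
        # small residual shape difference from wavelet support truncation
        assert cv.max() <= 5e-3


class TestEvokedInduced:
    def test_identical_sweeps_have_no_induced_power(self, rng):
        fs = 2000.0
        t = -0.25 + np.arange(1500) / fs
        sweep = gabor(t, 0.08, 0.02, 45.0, 5.0)
        ep = make_epochs(np.tile(sweep, (10, 1)), fs=fs)
        ei = evoked_induced_gamma(ep, BandSpec(baseline_span_s=2.0))
        assert ei.induced_raw <= 0.05 * ei.evoked_raw

    def test_fewer_than_two_sweeps_is_an_error(self):
        ep = make_epochs(np.zeros((1, 1500)), fs=2000.0)
        with pytest.raises(EmptyInputError):
            evoked_induced_gamma(ep)

    def test_stationary_noise_null_near_zero_db(self):
        # with no stimulus-locked structure both dB measures must sit
        # near 0 on average (baseline-correction null)
        from fxs_oscillo.preprocess import preprocess_recording
        vals = []
        for s in range(15):
            cfg = EffectConfig(n_stim=60, baseline_s=2.0, p20_amp=0.0,
                               n40_amp=0.0, evoked_burst_amp=0.0,
                               induced_burst_amp=0.0, artifact_rate=0.0)
            rec, _ = generate_recording(SubjectMeta("s", "WT", "M"),
                                        Session("vehicle"), cfg, seed=1000 + s)
            ep, _, _ = preprocess_recording(rec)
            ei = evoked_induced_gamma(ep, BandSpec(baseline_span_s=2.0))
            vals.append((ei.evoked_db, ei.induced_db))
        vals = np.array(vals)
        assert abs(vals[:, 0].mean()) <= 1.0
        assert abs(vals[:, 1].mean()) <= 1.0

    def test_single_trial_power_dominates_evoked(self, rng):
        # with residuals uncorrelated with the average, total single-trial
        # gamma power must be at least the evoked gamma power
        fs = 2000.0
        t = -0.25 + np.arange(1500) / fs
        data = np.array([
            gabor(t, 0.08, 0.02, 45.0, 4.0, phase=rng.uniform(0, 2 * np.pi))
            + rng.normal(0, 1.0, size=t.size)
            for _ in range(40)
        ])
        ep = make_epochs(data, fs=fs)
        bands = BandSpec(baseline_span_s=2.0)
        freqs, cycles = morlet_grid(bands)
        from fxs_oscillo.spectral import _wavelet
        fits = np.array([_wavelet(fs, f, c).size <= t.size
                         for f, c in zip(freqs, cycles)])
        total = morlet_power(data, fs, freqs[fits], cycles[fits]).mean(axis=1)
        gmask = (freqs[fits] >= 30) & (freqs[fits] <= 80)
        emask = (t >= 0.0) & (t <= 0.2)
        ei = evoked_induced_gamma(ep, bands)
        total_raw = total[np.ix_(gmask, emask)].mean()
        assert total_raw >= ei.evoked_raw
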