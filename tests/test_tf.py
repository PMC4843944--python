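"""Preprocessing and time-frequency tests, with direct-DFT and FFT oracles."""

import numpy as np
import pytest
from scipy.signal import get_window

from prestim import tf
from prestim.tf import (EpochSet, bandpass_filter, baseline_correct,
                        average_erp, measure_peaks, reject_artifacts,
                        wft_spectrogram)

FS = 1000.0


def make_epochs(data, energies=None, ratings=None, t0=-500.0):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(data=data, fs=FS, t0=t0, ch_names=["C4"],
                    energies=np.zeros(n, int) if energies is None else energies,
                    ratings=np.zeros(n) if ratings is None else ratings)


class TestBandpass:
    def test_dc_removed(self):
        x = np.full((1, 4000), 5.0)
        y = bandpass_filter(x, FS, 1.0, 100.0)
        assert np.max(np.abs(y[:, 1000:3000])) < 0.05

    def test_passband_amplitude_preserved(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 50.0 * t)[None, :]
        y = bandpass_filter(x, FS, 1.0, 100.0)
        amp = np.max(np.abs(y[:, 2000:6000]))
        assert abs(amp - 1.0) < 0.05

    def test_stopband_attenuated_fft_oracle(self):
        # 0.1 Hz tone: compare FFT amplitude at the tone bin before/after
        n = 40000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 0.1 * t)[None, :]
        y = bandpass_filter(x, FS, 1.0, 100.0)
        k = int(round(0.1 * n / FS))
        a_in = np.abs(np.fft.rfft(x[0]))[k]
        a_out = np.abs(np.fft.rfft(y[0]))[k]
        assert 20 * np.log10(a_in / a_out) >= 20.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros((1, 100)), FS, 1.0, 600.0)


class TestRejectArtifacts:
    def test_spike_trial_removed_others_kept(self):
        data = np.random.default_rng(0).normal(0, 10, (5, 1, 1500))
        data[2, 0, 700] = 150.0
        ep = make_epochs(data, ratings=np.arange(5.0))
        out = reject_artifacts(ep, 100.0)
        assert out.n_trials == 4
        assert 2 not in out.trial_ids
        assert np.array_equal(out.ratings, [0, 1, 3, 4])

    def test_identity_when_all_within_threshold(self):
        data = np.random.default_rng(1).uniform(-50, 50, (4, 1, 1500))
        ep = make_epochs(data)
        out = reject_artifacts(ep, 100.0)
        assert np.array_equal(out.data, ep.data)

    def test_idempotent(self):
        data = np.random.default_rng(2).uniform(-90, 90, (6, 1, 1500))
        data[4, 0, 100] = 130.0
        ep = make_epochs(data)
        once = reject_artifacts(ep, 100.0)
        twice = reject_artifacts(once, 100.0)
        assert np.array_equal(once.data, twice.data)

    def test_all_rejected_is_error(self):
        data = np.random.default_rng(3).normal(0, 40, (4, 1, 1500))
        ep = make_epochs(data)
        with pytest.raises(ValueError, match="no trials survive"):
            reject_artifacts(ep, 0.001)


class TestBaseline:
    def test_constant_trial_becomes_zero(self):
        ep = make_epochs(np.full((1, 1, 1500), 3.0))
        out = baseline_correct(ep, (-500.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_zero_mean_baseline_unchanged(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 5, (2, 1, 1500))
        t = np.arange(-500, 1000)
        pre = t <= 0
        data -= data[:, :, pre].mean(axis=2, keepdims=True)
        ep = make_epochs(data)
        out = baseline_correct(ep, (-500.0, 0.0))
        assert np.allclose(out.data, ep.data, atol=1e-12)

    def test_linear_ramp_closed_form(self):
        # ramp a*t: baseline mean over [-500, 0] is a*mean(t_interval)
        a = 0.02
        t = np.arange(-500.0, 1000.0)
        ep = make_epochs((a * t)[None, None, :])
        out = baseline_correct(ep, (-500.0, 0.0))
        expected = a * t - a * t[t <= 0].mean()
        assert np.allclose(out.data[0, 0], expected, atol=1e-12)

    def test_empty_interval_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 1500)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (2000.0, 3000.0))


def _wft_oracle(x, center, freq_hz, fs=FS, nwin=200, nfft=1000):
    """Direct tapered-DFT coefficient at one (t, f) point (reflect padding)."""
    half = nwin // 2
    xp = np.pad(x, (half, half), mode="reflect")
    seg = xp[center:center + nwin] * get_window("hann", nwin, fftbins=False)
    k = int(round(freq_hz * nfft / fs))
    n = np.arange(nwin)
    return np.sum(seg * np.exp(-2j * np.pi * k * n / nfft))


class TestWFT:
    def test_zero_input_zero_power(self):
        ep = make_epochs(np.zeros((2, 1, 1500)))
        spec = wft_spectrogram(ep)
        assert np.allclose(spec.power, 0.0)

    def test_sinusoid_peak_and_oracle_value(self):
        t = np.arange(-500, 1000) / 1000.0
        x = np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(x[None, None, :])
        spec = wft_spectrogram(ep)
        it = np.argmin(np.abs(spec.times - 300.0))     # interior time
        assert spec.freqs[np.argmax(spec.power[0, :, it])] == 10.0
        for f in (5.0, 10.0, 40.0):
            k = np.argmin(np.abs(spec.freqs - f))
            center = it  # 1 ms grid: index equals sample offset
            expected = np.abs(_wft_oracle(x, center, f)) ** 2
            assert abs(spec.power[0, k, it] - expected) <= 1e-8 * max(expected, 1e-12)

    def test_output_axes_cover_epoch_on_unit_grids(self):
        ep = make_epochs(np.zeros((1, 1, 1500)))
        spec = wft_spectrogram(ep, t_step_ms=1.0, f_step=1.0, f_max=100.0)
        assert spec.times[0] == -500.0 and spec.times[-1] == 999.0
        assert len(spec.times) == 1500
        assert np.array_equal(spec.freqs, np.arange(1.0, 101.0))

    def test_matches_bruteforce_oracle_on_random_trials(self, rng):
        x = rng.normal(0, 1, (3, 1, 1500))
        ep = make_epochs(x)
        spec = wft_spectrogram(ep, t_step_ms=250.0)
        for tr in range(3):
            for it, c in enumerate(range(0, 1500, 250)):
                for f in (1.0, 13.0, 87.0):
                    k = np.argmin(np.abs(spec.freqs - f))
                    expected = np.abs(_wft_oracle(x[tr, 0], c, f)) ** 2
                    got = spec.power[tr, k, it]
                    assert abs(got - expected) <= 1e-8 * max(expected, 1e-12)

    def test_parseval_boxcar_variant(self):
        # stationary multi-tone segment: power summed over the 1..100 Hz grid
        # (x2 for conjugate bins) tracks N * sum(x^2) within 10 %
        rng = np.random.default_rng(6)
        t = np.arange(-500, 1000) / 1000.0
        x = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                for f in (10.0, 25.0, 40.0, 60.0, 95.0))
        ep = make_epochs(x[None, None, :])
        spec = wft_spectrogram(ep, taper="boxcar", t_step_ms=100.0)
        it = np.argmin(np.abs(spec.times - 200.0))
        c = int(spec.times[it] - ep.t0)
        seg = x[c - 100:c + 100]
        total = 2 * spec.power[0, :, it].sum()
        expected = 1000.0 * np.sum(seg ** 2)
        assert abs(total - expected) / expected < 0.10

    def test_edge_leakage_of_poststimulus_burst(self):
        # a purely poststimulus burst leaks into the last 100 prestimulus ms
        t = np.arange(-500, 1000)
        x = np.where((t >= 40) & (t <= 80),
                     np.sin(2 * np.pi * 20.0 * t / 1000.0), 0.0)
        ep = make_epochs(x[None, None, :])
        spec = wft_spectrogram(ep)
        k = np.argmin(np.abs(spec.freqs - 20.0))
        near = spec.power[0, k, np.argmin(np.abs(spec.times - (-50.0)))]
        far = spec.power[0, k, np.argmin(np.abs(spec.times - (-400.0)))]
        assert near > 10 * max(far, 1e-30)

    def test_edge_flag_marks_padded_estimates(self):
        ep = make_epochs(np.zeros((1, 1, 1500)))
        spec = wft_spectrogram(ep)
        assert spec.edge_flag[:100].all() and spec.edge_flag[-99:].all()
        assert not spec.edge_flag[100:-99].any()


class TestERPAndPeaks:
    def test_average_identical_trials(self):
        x = np.random.default_rng(7).normal(0, 1, 1500)
        ep = make_epochs(np.stack([x, x])[:, None, :])
        erp = average_erp(ep)
        assert np.allclose(erp[0][0], x)

    def test_opposite_trials_cancel(self):
        x = np.random.default_rng(8).normal(0, 1, 1500)
        ep = make_epochs(np.stack([x, -x])[:, None, :])
        assert np.allclose(average_erp(ep)[0], 0.0)

    def test_default_design_yields_four_waveforms(self, default_subject):
        epochs, _ = default_subject
        erp = average_erp(epochs)
        assert sorted(erp) == [0, 1, 2, 3]

    def test_analytic_sine_extrema(self):
        t = np.arange(-500.0, 1000.0)
        w = -np.sin(2 * np.pi * (t - 150.0) / 400.0)
        pk = measure_peaks(np.where((t >= 150) & (t <= 550), w, 0.0), t)
        assert abs(pk.n2_latency - 250.0) <= 1.0
        assert abs(pk.p2_latency - 450.0) <= 1.0

    def test_planted_peaks_recovered_under_noise(self):
        # residual noise on an averaged evoked waveform is low-frequency:
        # smooth (25 ms correlation) noise at 10 % of the N2 peak amplitude
        from scipy.ndimage import gaussian_filter1d

        t = np.arange(-500.0, 1000.0)
        clean = (-10.0 * np.exp(-0.5 * ((t - 200) / 15.0) ** 2)
                 + 8.0 * np.exp(-0.5 * ((t - 350) / 20.0) ** 2))
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            noise = gaussian_filter1d(rng.standard_normal(t.size), 25.0)
            noise *= 1.0 / noise.std()
            pk = measure_peaks(clean + noise, t)
            hits += (abs(pk.n2_latency - 200.0) <= 5.0
                     and abs(pk.p2_latency - 350.0) <= 5.0)
        assert hits >= 95

    def test_default_window_is_150_to_500(self):
        assert tf.PEAK_WINDOW_MS == (150.0, 500.0)

    def test_monotone_waveform_flagged(self):
        t = np.arange(-500.0, 1000.0)
        pk = measure_peaks(0.01 * t, t)
        assert pk.low_confidence
        assert pk.n2_latency == 150.0 and pk.p2_latency == 500.0
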