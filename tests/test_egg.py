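"""EGG preprocessing: resampling, spectra, peak detection, filtering, QC."""

import numpy as np
import pytest
from scipy import signal

from gastrosync import (EGGRecording, GastricPeak, QualityReport,
                        assess_egg_quality, bandpass_around_peak,
                        find_gastric_peak, resample_signal,
                        select_gastric_channel, welch_spectrum)
from gastrosync.synthetic import _one_over_f


def sine_rec(freqs, fs=10.0, duration=900.0, amps=None):
    t = np.arange(int(duration * fs)) / fs
    amps = amps or [1.0] * len(freqs)
    rows = [a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps)]
    return EGGRecording(samples=np.sum(rows, axis=0)[None, :], fs=fs)


class TestResample:
    def test_constant_vector_stays_constant_with_scaled_length(self):
        x = np.full(5000, 3.7)
        y = resample_signal(x, 5000.0, 10.0)
        assert y.size == round(5000 * 10 / 5000)
        assert np.allclose(y, 3.7, atol=1e-6)

    def test_in_band_sine_amplitude_preserved_within_1pct(self):
        fs_in, fs_out = 5000.0, 10.0
        t = np.arange(int(600 * fs_in)) / fs_in
        x = np.sin(2 * np.pi * 0.05 * t)
        y = resample_signal(x, fs_in, fs_out)
        mid = slice(y.size // 4, 3 * y.size // 4)
        amp = np.sqrt(2) * y[mid].std()
        assert abs(amp - 1.0) < 0.01

    def test_antialias_removes_out_of_band_power(self, rng):
        x = rng.standard_normal(200_000)
        y = resample_signal(x, 5000.0, 10.0)
        # white noise at 5 kHz has only 10/5000 of its power below 5 Hz
        assert y.var() < 0.1 * x.var()

    @pytest.mark.parametrize("fs_in,fs_out", [(0, 10), (10, 0), (-5, 1)])
    def test_nonpositive_rates_rejected(self, fs_in, fs_out):
        with pytest.raises(ValueError):
            resample_signal(np.zeros(100), fs_in, fs_out)


class TestWelch:
    def test_pure_sine_peak_at_its_frequency_bin(self):
        spec = welch_spectrum(sine_rec([0.05]))
        assert spec.freqs[np.argmax(spec.power[0])] == pytest.approx(0.05)
        assert spec.df == pytest.approx(1 / 200.0)

    def test_two_sines_give_two_local_maxima(self):
        spec = welch_spectrum(sine_rec([0.05, 0.2]))
        p = spec.power[0]
        for f in (0.05, 0.2):
            j = np.argmin(np.abs(spec.freqs - f))
            assert p[j] > p[j - 1] and p[j] > p[j + 1]

    def test_white_noise_spectrum_flat_within_monte_carlo_error(self, rng):
        # mean Welch PSD over realizations; flatness relative to the
        # periodogram sampling error of the averaged estimate
        n_real, fs, dur = 60, 10.0, 900.0
        powers = []
        for _ in range(n_real):
            rec = EGGRecording(rng.standard_normal(int(fs * dur))[None, :], fs)
            powers.append(welch_spectrum(rec).power[0])
        mean_p = np.mean(powers, axis=0)[2:-2]
        n_seg = 15  # (900 - 150) / 50 segments per realization
        rel_sd = 1 / np.sqrt(n_real * n_seg)
        assert mean_p.std() / mean_p.mean() < 4 * rel_sd

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_spectrum(sine_rec([0.05], duration=100.0))

    def test_in_band_power_independent_of_overlap(self):
        rec = sine_rec([0.05])
        p_default = welch_spectrum(rec, 200, 150)
        p_less = welch_spectrum(rec, 200, 100)
        def band_power(spec):
            sel = (spec.freqs >= 0.033) & (spec.freqs <= 0.066)
            return np.trapezoid(spec.power[0, sel], spec.freqs[sel])
        assert band_power(p_less) == pytest.approx(band_power(p_default), rel=0.05)


class TestFindPeak:
    def test_single_sine_peak_found(self):
        spec = welch_spectrum(sine_rec([0.05]))
        peaks = find_gastric_peak(spec)
        assert peaks[0].peak_freq == pytest.approx(0.05)
        assert peaks[0].is_clear

    def test_two_channels_independent_peaks(self):
        fs, t = 10.0, np.arange(9000) / 10.0
        samples = np.vstack([np.sin(2 * np.pi * 0.04 * t),
                             np.sin(2 * np.pi * 0.06 * t)])
        spec = welch_spectrum(EGGRecording(samples, fs))
        peaks = find_gastric_peak(spec)
        assert peaks[0].peak_freq == pytest.approx(0.04)
        assert peaks[1].peak_freq == pytest.approx(0.06)

    def test_one_over_f_noise_flagged_low_prominence(self, rng):
        x = _one_over_f(rng, 9000, 1.0)
        spec = welch_spectrum(EGGRecording(x, 10.0))
        peaks = find_gastric_peak(spec)
        assert not peaks[0].is_clear

    def test_band_outside_spectrum_rejected(self):
        spec = welch_spectrum(sine_rec([0.05]))
        with pytest.raises(ValueError):
            find_gastric_peak(spec, band=(4.0, 6.0))


def mkpeak(ch, power, freq=0.05, clear=True):
    return GastricPeak(channel=ch, peak_freq=freq, peak_power=power,
                       search_band=(0.033, 0.066), is_clear=clear)


def mkreport(level):
    ok = level == 1
    return QualityReport(level=level, clear_peak=True,
                         channel_consistency=ok, run_consistency=ok)


class TestChannelSelection:
    def test_largest_peak_power_wins_by_default(self):
        peaks = [mkpeak(0, 3.0), mkpeak(1, 1.0), mkpeak(2, 2.0)]
        ch, _ = select_gastric_channel(peaks)
        assert ch == 0

    def test_second_largest_preferred_when_strictly_better_quality(self):
        peaks = [mkpeak(0, 3.0), mkpeak(1, 2.0)]
        ch, _ = select_gastric_channel(peaks, quality=[mkreport(2), mkreport(1)])
        assert ch == 1

    def test_override_wins(self):
        peaks = [mkpeak(0, 3.0), mkpeak(1, 1.0), mkpeak(2, 2.0)]
        ch, _ = select_gastric_channel(peaks, override=2)
        assert ch == 2

    def test_no_clear_peak_refuses_selection(self):
        peaks = [mkpeak(0, 3.0, clear=False), mkpeak(1, 1.0, clear=False)]
        with pytest.raises(ValueError, match="level 3"):
            select_gastric_channel(peaks)


class TestBandpass:
    fs = 10.0

    def test_passband_sine_amplitude_preserved(self):
        t = np.arange(9000) / self.fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass_around_peak(x, self.fs, 0.05)
        mid = slice(2000, 7000)
        assert np.sqrt(2) * y[mid].std() == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_component_attenuated_20db(self):
        t = np.arange(9000) / self.fs
        x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
        y = bandpass_around_peak(x, self.fs, 0.05)
        mid = slice(2000, 7000)
        f, p = signal.periodogram(y[mid], self.fs)
        band = lambda lo, hi: p[(f >= lo) & (f <= hi)].sum()
        assert band(0.18, 0.22) < 1e-2 * band(0.035, 0.065)

    def test_zero_vector_passes_through(self):
        assert np.allclose(bandpass_around_peak(np.zeros(1000), self.fs, 0.05), 0)

    def test_idempotent_on_in_band_content(self):
        # components well inside the flat passband region
        t = np.arange(9000) / self.fs
        x = sum(np.sin(2 * np.pi * f * t + p)
                for f, p in [(0.045, 0.3), (0.05, 1.1), (0.055, 2.0)])
        once = bandpass_around_peak(x, self.fs, 0.05)
        twice = bandpass_around_peak(once, self.fs, 0.05)
        mid = slice(1500, 7500)
        rms = np.sqrt(np.mean((twice[mid] - once[mid]) ** 2))
        assert rms <= 0.01 * np.sqrt(np.mean(once[mid] ** 2))

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_around_peak(np.zeros(100), 0.1, 0.05, halfwidth=0.015)


class TestQuality:
    def spec_and_peaks(self, freqs_per_run, clear=True):
        specs, peaks = [], []
        for freqs in freqs_per_run:
            specs.append(None)
            peaks.append([mkpeak(i, 1.0 + (len(freqs) - i) * 0.1, f, clear)
                          for i, f in enumerate(freqs)])
        return specs, peaks

    def test_all_criteria_met_is_level_1(self):
        specs, peaks = self.spec_and_peaks([[0.050, 0.052], [0.050, 0.051]])
        rep = assess_egg_quality(specs, peaks)
        assert rep.level == 1 and not rep.excluded

    def test_no_clear_peak_is_level_3_excluded(self):
        specs, peaks = self.spec_and_peaks([[0.050, 0.052]], clear=False)
        rep = assess_egg_quality(specs, peaks)
        assert rep.level == 3 and rep.excluded

    def test_channel_spread_above_tolerance_is_level_2(self):
        specs, peaks = self.spec_and_peaks([[0.040, 0.055]])
        rep = assess_egg_quality(specs, peaks, consistency_tol=0.01)
        assert rep.level == 2 and not rep.channel_consistency

    def test_run_inconsistency_is_level_2(self):
        specs, peaks = self.spec_and_peaks([[0.040], [0.060]])
        rep = assess_egg_quality(specs, peaks, consistency_tol=0.01)
        assert rep.level == 2 and not rep.run_consistency

    def test_level_1_requires_all_criteria(self):
        with pytest.raises(ValueError):
            QualityReport(level=1, clear_peak=True,
                          channel_consistency=False, run_consistency=True)
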