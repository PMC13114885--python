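"""Deterministic EEG quantification: filtering, BSR, SEF, Welch, binning."""

import numpy as np
import pytest

from pndeeg.eegsignal import (
    DEFAULT_BANDS,
    ConfigurationError,
    EEGRecording,
    InputError,
    band_powers,
    bandpass,
    burst_suppression_ratio,
    emergence_bins,
    spectral_edge_frequency,
    welch_psd,
)

from conftest import sinusoid


def bsr_bruteforce(x: np.ndarray, fs: float, thr: float = 5.0,
                   min_dur: float = 0.5) -> float:
    """Independent per-sample run-length oracle for the suppression ratio."""
    min_len = int(np.ceil(min_dur * fs))
    count = run = 0
    for v in np.abs(x) <= thr:
        if v:
            run += 1
        else:
            if run >= min_len:
                count += run
            run = 0
    if run >= min_len:
        count += run
    return 100.0 * count / len(x)


class TestBandpass:
    def test_passband_gain_near_unity(self):
        rec = sinusoid(10.0, 30.0)
        out = bandpass(rec)
        mid = out.samples[5000:-5000]
        assert abs(mid.max() - 1.0) < 0.02
        assert len(out.samples) == len(rec.samples)

    def test_dc_offset_removed(self):
        rec = EEGRecording(np.full(30_000, 100.0), 1000.0)
        out = bandpass(rec)
        assert abs(out.samples.mean()) < 0.5

    def test_stopband_attenuation_at_60hz_matches_design(self):
        from scipy import signal as sps

        rec = sinusoid(60.0, 30.0)
        out = bandpass(rec)
        mid = slice(2000, -2000)  # exclude filter edge transients
        measured = np.sqrt(np.mean(out.samples[mid] ** 2)) / np.sqrt(
            np.mean(rec.samples[mid] ** 2))
        # oracle: the design's own frequency response; forward-backward
        # application squares the magnitude
        sos = sps.butter(4, [1, 48], btype="bandpass", fs=1000.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[60.0], fs=1000.0)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.02)
        assert measured < 0.2

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError):
            bandpass(EEGRecording(np.zeros(50), 1000.0))

    def test_invalid_band_rejected(self):
        with pytest.raises(InputError):
            bandpass(sinusoid(10, 2), low=48, high=1)


class TestBurstSuppressionRatio:
    def test_all_zero_signal_fully_suppressed(self):
        assert burst_suppression_ratio(EEGRecording(np.zeros(5000), 1000.0)) == 100.0

    def test_large_sinusoid_matches_bruteforce(self):
        rec = sinusoid(10.0, 10.0, amplitude=50.0)
        got = burst_suppression_ratio(rec)
        assert got == pytest.approx(
            bsr_bruteforce(rec.samples, rec.sample_rate))
        assert got == 0.0  # zero-crossing dwell below threshold is ~3 ms

    def test_half_suppressed_construction(self):
        rng = np.random.default_rng(0)
        noisy = 50.0 * np.sign(rng.standard_normal(5000))
        x = np.concatenate([np.zeros(5000), noisy])
        assert burst_suppression_ratio(
            EEGRecording(x, 1000.0)) == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_signal_matches_bruteforce_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = 6.0 * rng.standard_normal(8000)
        x[2000:2800] = 0.1 * rng.standard_normal(800)
        got = burst_suppression_ratio(EEGRecording(x, 1000.0))
        assert got == pytest.approx(bsr_bruteforce(x, 1000.0))
        assert 0.0 <= got <= 100.0

    def test_concatenation_near_additive(self):
        rng = np.random.default_rng(1)
        a = 30.0 * rng.standard_normal(10_000)
        b = np.zeros(10_000)
        whole = burst_suppression_ratio(EEGRecording(np.concatenate([a, b]), 1000.0))
        parts = 0.5 * (burst_suppression_ratio(EEGRecording(a, 1000.0))
                       + burst_suppression_ratio(EEGRecording(b, 1000.0)))
        # boundary-run tolerance: one min_dur run over the total length
        assert abs(whole - parts) <= 100.0 * 500 / 20_000

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InputError):
            burst_suppression_ratio(sinusoid(10, 1), threshold=-1)
        with pytest.raises(InputError):
            burst_suppression_ratio(sinusoid(10, 1), min_dur=0)


class TestSpectralEdgeFrequency:
    def test_pure_sinusoid_edge_at_line(self):
        sef = spectral_edge_frequency(sinusoid(10.0, 10.0))
        assert np.all(np.abs(sef - 10.0) <= 1.0)  # 1 Hz bin width

    def test_two_line_spectrum_crosses_at_second_line(self):
        # 5 Hz carries 90% of power, 40 Hz 10%: cumulative reaches 95%
        # only once the second line is included
        t = np.arange(10_000) / 1000.0
        x = np.sqrt(0.90) * np.sin(2 * np.pi * 5 * t) \
            + np.sqrt(0.10) * np.sin(2 * np.pi * 40 * t)
        sef = spectral_edge_frequency(EEGRecording(x, 1000.0))
        assert np.all(np.abs(sef - 40.0) <= 1.0)

    def test_quantile_one_is_highest_nonzero_bin(self):
        sef = spectral_edge_frequency(sinusoid(10.0, 5.0), quantile=1.0)
        assert np.all(sef >= 10.0)

    def test_all_zero_slice_reported_missing(self):
        sef = spectral_edge_frequency(EEGRecording(np.zeros(3000), 1000.0))
        assert np.isnan(sef).all()

    def test_adding_high_frequency_power_never_lowers_edge(self):
        t = np.arange(20_000) / 1000.0
        base = np.sin(2 * np.pi * 6 * t)
        rich = base + 0.8 * np.sin(2 * np.pi * 35 * t)
        s0 = spectral_edge_frequency(EEGRecording(base, 1000.0))
        s1 = spectral_edge_frequency(EEGRecording(rich, 1000.0))
        assert np.all(s1 >= s0 - 1e-9)


class TestWelchPSD:
    def test_white_noise_power_conservation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(600_000)
        prof = welch_psd(EEGRecording(x, 1000.0))
        df = prof.freqs[1] - prof.freqs[0]
        assert prof.psd.sum() * df == pytest.approx(np.var(x), rel=0.05)
        assert df == pytest.approx(0.5)

    def test_sinusoid_peak_power(self):
        A = 3.0
        prof = welch_psd(sinusoid(10.0, 60.0, amplitude=A))
        df = prof.freqs[1] - prof.freqs[0]
        peak = np.abs(prof.freqs - 10.0) <= 1.0
        assert prof.psd[peak].sum() * df == pytest.approx(A ** 2 / 2, rel=0.02)

    def test_amplitude_scaling_squares_psd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        p1 = welch_psd(EEGRecording(x, 1000.0)).psd
        p2 = welch_psd(EEGRecording(3.0 * x, 1000.0)).psd
        np.testing.assert_allclose(p2, 9.0 * p1, rtol=1e-10)

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            welch_psd(EEGRecording(np.zeros(1500), 1000.0))


class TestBandPowers:
    def test_alpha_sinusoid_concentrates_in_alpha(self):
        prof = band_powers(welch_psd(sinusoid(10.0, 30.0)))
        assert prof.band_ratios["alpha"] >= 0.95

    @pytest.mark.parametrize("seed", range(3))
    def test_ratios_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        prof = band_powers(welch_psd(
            EEGRecording(rng.standard_normal(8000), 1000.0)))
        assert sum(prof.band_ratios.values()) == pytest.approx(1.0, abs=1e-9)

    def test_two_line_symmetry_between_delta_and_beta(self):
        t = np.arange(60_000) / 1000.0
        x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 20 * t)
        prof = band_powers(welch_psd(EEGRecording(x, 1000.0)))
        assert prof.band_ratios["delta"] == pytest.approx(0.5, abs=0.02)
        assert prof.band_ratios["beta"] == pytest.approx(0.5, abs=0.02)

    def test_ratios_invariant_to_amplitude_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(8000)
        r1 = band_powers(welch_psd(EEGRecording(x, 1000.0))).band_ratios
        r2 = band_powers(welch_psd(EEGRecording(7.5 * x, 1000.0))).band_ratios
        for b in r1:
            assert r1[b] == pytest.approx(r2[b], abs=1e-12)

    def test_gapped_bands_rejected(self):
        prof = welch_psd(sinusoid(10.0, 4.0))
        with pytest.raises(ConfigurationError):
            band_powers(prof, bands={"lo": (1, 4), "hi": (8, 30)})


class TestEmergenceBins:
    def _rec(self, duration, fs=1000.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(duration * fs)) * 20
        return EEGRecording(x, fs, phase_intervals={"emergence": (0.0, duration)})

    def test_150s_interval_tiles_exactly(self):
        traj = emergence_bins(self._rec(150.0))
        assert len(traj.segments) == 10
        assert all(len(s.samples) == 15_000 for s in traj.segments)
        # contiguity: segments are exactly the 10 consecutive 15 s windows
        rec = self._rec(150.0)
        traj = emergence_bins(rec)
        for i, seg in enumerate(traj.segments):
            np.testing.assert_array_equal(
                seg.samples, rec.samples[i * 15_000:(i + 1) * 15_000])

    def test_300s_interval_centers_segments(self):
        rec = self._rec(300.0)
        traj = emergence_bins(rec)
        assert traj.bin_duration == pytest.approx(30.0)
        np.testing.assert_array_equal(
            traj.segments[0].samples, rec.samples[7500:7500 + 15_000])

    def test_stationary_signal_flat_trajectory(self):
        from pndeeg.synth import SyntheticConfig, gen_eeg

        rec = gen_eeg(SyntheticConfig(), "baseline", "preserved", 150.0, seed=3)
        rec.phase_intervals = {"emergence": (0.0, 150.0)}
        traj = emergence_bins(rec)
        deltas = [p.band_ratios["delta"] for p in traj.per_bin_spectra]
        assert max(deltas) - min(deltas) < 0.08

    def test_short_interval_error_names_shortfall(self):
        with pytest.raises(InputError, match="short"):
            emergence_bins(self._rec(120.0))

    def test_missing_interval_rejected(self):
        rec = EEGRecording(np.zeros(200_000), 1000.0)
        with pytest.raises(InputError):
            emergence_bins(rec)

    def test_arousal_grid_is_percent_decades(self):
        traj = emergence_bins(self._rec(150.0))
        np.testing.assert_allclose(traj.arousal_grid, np.arange(10, 101, 10))


def test_operations_are_deterministic():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(20_000) * 15
    rec = EEGRecording(x, 1000.0)
    assert burst_suppression_ratio(rec) == burst_suppression_ratio(rec)
    np.testing.assert_array_equal(bandpass(rec).samples, bandpass(rec).samples)
    np.testing.assert_array_equal(welch_psd(rec).psd, welch_psd(rec).psd)
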