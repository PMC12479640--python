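"""Acoustic feature pipeline against analytic and brute-force oracles."""

import numpy as np
import pytest

from swallowsound.acoustics import (
    FeatureUndefinedError,
    FilterSpec,
    FrameSpec,
    extract_profile,
    frame,
    highpass,
    peak_amplitude_db,
    peak_frequency,
    peak_power_db,
    welch_psd,
)
from swallowsound.audio_io import AudioSignal, SwallowInterval, detect_clips

from conftest import make_tone

FS = 44_100
DEFAULT_F = FilterSpec()
DEFAULT_FR = FrameSpec()
FRAME_LEN = DEFAULT_FR.frame_length(FS)  # 882
SUBFRAME_LEN = DEFAULT_FR.subframe_length(FRAME_LEN)  # 160
BIN_HZ = FS / SUBFRAME_LEN  # Welch grid spacing


def welch_oracle(x: np.ndarray, nperseg: int, fs: float) -> np.ndarray:
    """Explicit-DFT averaged modified periodogram (independent of scipy).

    Hann-windowed half-overlapping sub-frames; one-sided density scaling;
    returned normalized to unit sum.
    """
    x = np.asarray(x, dtype=np.float64)
    step = nperseg - nperseg // 2
    n = np.arange(nperseg)
    win = 0.5 * (1 - np.cos(2 * np.pi * n / nperseg))  # periodic Hann
    k = np.arange(nperseg // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / nperseg)  # explicit DFT
    segs = [x[s:s + nperseg]
            for s in range(0, x.size - nperseg + 1, step)]
    psds = []
    for seg in segs:
        spec = dft @ (win * seg)
        p = np.abs(spec) ** 2 / (fs * np.sum(win ** 2))
        p[1:] *= 2
        if nperseg % 2 == 0:
            p[-1] /= 2
        psds.append(p)
    avg = np.mean(psds, axis=0)
    return avg / avg.sum()


class TestHighpass:
    def test_dc_is_rejected(self):
        sig = AudioSignal(np.full(FS, 1000, dtype=np.int16), FS)
        y = highpass(sig, DEFAULT_F)
        assert np.max(np.abs(y[-1000:])) < 1.0  # < 1 LSB after transient

    def test_cutoff_gain_is_minus_3db(self):
        sig = make_tone(400.0, 1.0, 10_000)
        y = highpass(sig, DEFAULT_F)
        steady = y[FS // 2:]
        gain_db = 20 * np.log10(np.sqrt(np.mean(steady ** 2))
                                / (10_000 / np.sqrt(2)))
        assert gain_db == pytest.approx(-3.01, abs=0.2)

    def test_passband_gain_matches_closed_form(self):
        # |H(f)|^2 = (f/fc)^8 / (1 + (f/fc)^8) for a 4th-order Butterworth
        sig = make_tone(2000.0, 1.0, 10_000)
        y = highpass(sig, DEFAULT_F)
        steady = y[FS // 2:]
        gain_db = 10 * np.log10(np.mean(steady ** 2) / (10_000 ** 2 / 2))
        ratio = (2000 / 400) ** 8
        expected_db = 10 * np.log10(ratio / (1 + ratio))
        assert gain_db == pytest.approx(expected_db, abs=0.1)

    def test_cutoff_above_nyquist_rejected(self):
        sig = make_tone(100.0, 0.1, 1000, fs=8000)
        with pytest.raises(ValueError, match="fs/2"):
            highpass(sig, FilterSpec(cutoff_hz=5000.0))


class TestFraming:
    @pytest.mark.parametrize(
        "n_samples, expected_frames",
        [
            (882, 1),
            (1764, 3),
            (37_485, 84),  # 0.85 s of audio: 1 + (37485-882)//441
        ],
    )
    def test_frame_count(self, n_samples, expected_frames):
        frames = frame(np.ones(n_samples), DEFAULT_FR, FS)
        assert frames.shape == (expected_frames, FRAME_LEN)

    def test_short_segment_rejected_not_padded(self):
        with pytest.raises(FeatureUndefinedError, match="shorter than one"):
            frame(np.ones(FRAME_LEN - 1), DEFAULT_FR, FS)


class TestWelchPsd:
    def test_matches_explicit_dft_oracle(self):
        rng = np.random.default_rng(11)
        for n in (160, 512, 882, 1024):
            x = rng.standard_normal(n)
            est = welch_psd(x, DEFAULT_FR, FS)
            expected = welch_oracle(x, DEFAULT_FR.subframe_length(n), FS)
            assert est.psd.shape == expected.shape
            np.testing.assert_allclose(est.psd, expected, rtol=1e-9)

    def test_unit_sum_normalization(self):
        rng = np.random.default_rng(3)
        est = welch_psd(rng.standard_normal(FRAME_LEN), DEFAULT_FR, FS)
        assert est.normalized
        assert est.psd.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tone_concentrates_power_at_its_bin(self):
        t = np.arange(FRAME_LEN) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        est = welch_psd(x, DEFAULT_FR, FS)
        peak_bin_hz = est.frequencies_hz[np.argmax(est.psd)]
        assert abs(peak_bin_hz - 1000.0) <= BIN_HZ

    def test_white_noise_psd_is_flat_after_averaging(self):
        rng = np.random.default_rng(5)
        welch_avg = np.mean(
            [welch_psd(rng.standard_normal(FRAME_LEN), DEFAULT_FR, FS).psd
             for _ in range(200)], axis=0)
        lo, hi = np.percentile(
            np.arange(welch_avg.size), [5, 95]).astype(int)
        interior = welch_avg[lo:hi + 1]
        assert interior.max() / interior.min() < 4.0

    def test_welch_variance_below_single_periodogram(self):
        # the point of sub-frame averaging: lower per-bin variance than a
        # single unaveraged periodogram on the same grid
        rng = np.random.default_rng(6)
        frames = rng.standard_normal((200, FRAME_LEN))
        welch = np.array(
            [welch_psd(f, DEFAULT_FR, FS).psd for f in frames])
        single = np.array(
            [welch_oracle(f[:SUBFRAME_LEN], SUBFRAME_LEN, FS)
             for f in frames])
        interior = slice(5, -5)
        assert (welch[:, interior].var(axis=0).mean()
                < single[:, interior].var(axis=0).mean())

    def test_zero_frame_flagged_not_uniform(self):
        est = welch_psd(np.zeros(FRAME_LEN), DEFAULT_FR, FS)
        assert est.zero_energy
        assert not est.normalized
        assert np.all(est.psd == 0)


class TestPeakFrequency:
    def test_single_tone_recovered_within_two_bins(self):
        rng = np.random.default_rng(2)
        t = np.arange(int(0.5 * FS)) / FS
        x = 20_000 * np.sin(2 * np.pi * 1500.0 * t)
        x += 200 * rng.standard_normal(t.size)  # -40 dB white noise
        sig = AudioSignal(np.rint(x).astype(np.int16), FS)
        f = peak_frequency(sig)
        assert abs(f - 1500.0) <= 2 * BIN_HZ

    def test_cdf_crosses_inside_dominant_peak(self):
        # 96% of power at 1 kHz, 4% at 5 kHz: the 0.95 crossing stays in
        # the first peak
        t = np.arange(int(0.5 * FS)) / FS
        x = (np.sqrt(0.96) * np.sin(2 * np.pi * 1000.0 * t)
             + np.sqrt(0.04) * np.sin(2 * np.pi * 5000.0 * t))
        sig = AudioSignal(np.rint(20_000 * x).astype(np.int16), FS)
        f = peak_frequency(sig)
        assert abs(f - 1000.0) <= 2 * BIN_HZ

    def test_band_limited_noise_gives_band_percentile(self):
        # uniform band 400-2000 Hz: the 95% crossing sits near
        # 400 + 0.95*1600 = 1920 Hz
        rng = np.random.default_rng(9)
        crossings = []
        n = int(0.85 * FS)
        freqs = np.fft.rfftfreq(n, 1 / FS)
        band = (freqs >= 400) & (freqs <= 2000)
        for _ in range(100):
            spec = np.zeros(freqs.size, dtype=complex)
            phases = rng.uniform(0, 2 * np.pi, band.sum())
            spec[band] = np.exp(1j * phases)
            x = np.fft.irfft(spec, n)
            x *= 20_000 / np.abs(x).max()
            sig = AudioSignal(np.rint(x).astype(np.int16), FS)
            crossings.append(peak_frequency(sig))
        assert np.mean(crossings) == pytest.approx(1920.0, abs=100.0)

    def test_scale_invariance_to_the_bin(self, tone_segment):
        f1 = peak_frequency(tone_segment)
        scaled = AudioSignal(
            (tone_segment.samples.astype(np.int32) // 8).astype(np.int16), FS)
        assert peak_frequency(scaled) == f1

    def test_zero_energy_segment_rejected(self):
        sig = AudioSignal(np.zeros(FS, dtype=np.int16), FS)
        with pytest.raises(FeatureUndefinedError, match="zero-energy"):
            peak_frequency(sig)


class TestPeakAmplitude:
    @pytest.mark.parametrize(
        "peak, expected_db",
        [
            (32_767, 90.31),  # 16-bit full scale
            (1, 0.0),  # the LSB reference point
            (16_384, 84.29),
        ],
    )
    def test_db_re_one_lsb(self, peak, expected_db):
        sig = AudioSignal(
            np.array([0, peak, 0], dtype=np.int16), FS)
        assert peak_amplitude_db(sig) == pytest.approx(expected_db, abs=0.005)

    def test_all_zero_rejected(self):
        with pytest.raises(FeatureUndefinedError):
            peak_amplitude_db(AudioSignal(np.zeros(10, dtype=np.int16), FS))


class TestPeakPower:
    def test_sine_power_closed_form(self):
        # mean-square power of a sine of amplitude A is A^2/2
        sig = make_tone(2000.0, 0.5, 30_000)
        db, n_clipped = peak_power_db(sig)
        assert n_clipped == 0
        assert db == pytest.approx(10 * np.log10(30_000 ** 2 / 2), abs=0.1)

    def test_constant_one_lsb_reference(self):
        sig = AudioSignal(np.ones(FRAME_LEN * 2, dtype=np.int16), FS)
        db, _ = peak_power_db(sig, filtered=False)
        assert db == pytest.approx(0.0, abs=1e-9)

    def test_clip_removal_leaves_power_unchanged(self):
        # alternate samples forced to full scale; censoring them recovers
        # the clip-free estimate
        clean = make_tone(2000.0, 0.5, 20_000)
        corrupted = clean.samples.astype(np.int32).copy()
        corrupted[::2] = np.where(corrupted[::2] >= 0, 32_767, -32_767)
        dirty = AudioSignal(corrupted, FS, bit_depth=32)
        clip = detect_clips(dirty, clip_threshold=32_767)
        db_dirty, n_removed = peak_power_db(dirty, clip=clip)
        db_clean, _ = peak_power_db(clean)
        assert n_removed == clip.n_clipped > 0
        assert db_dirty == pytest.approx(db_clean, abs=0.1)

    def test_fully_clipped_segment_rejected(self):
        sig = AudioSignal(np.full(FRAME_LEN * 2, 32_767, dtype=np.int16), FS)
        with pytest.raises(FeatureUndefinedError, match="unclipped samples"):
            peak_power_db(sig)


class TestProfileInvariants:
    def test_power_never_exceeds_amplitude_on_clipfree_signals(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            x = rng.normal(0, 3000, int(0.3 * FS))
            sig = AudioSignal(
                np.clip(np.rint(x), -32_000, 32_000).astype(np.int16), FS)
            amp = peak_amplitude_db(sig)
            power, _ = peak_power_db(sig, filtered=False)
            assert power <= amp + 1e-9

    def test_db_shift_under_scaling(self):
        sig = make_tone(2000.0, 0.3, 4000)
        scaled = AudioSignal((sig.samples.astype(np.int32) * 4), FS,
                             bit_depth=32)
        assert peak_amplitude_db(scaled) == pytest.approx(
            peak_amplitude_db(sig) + 20 * np.log10(4), abs=0.05)
        assert peak_power_db(scaled)[0] == pytest.approx(
            peak_power_db(sig)[0] + 20 * np.log10(4), abs=0.05)

    def test_extract_profile_duration_and_reason_codes(self):
        sig = make_tone(1678.0, 0.85, 25_000)
        iv = SwallowInterval("r", "s", 1.00, 1.85)
        prof = extract_profile(sig, iv)
        assert prof.duration_s == pytest.approx(0.85)
        assert not prof.reasons

        silent = AudioSignal(np.zeros(int(0.85 * FS), dtype=np.int16), FS)
        prof = extract_profile(silent, iv)
        assert np.isnan(prof.peak_amplitude_db)
        assert "peak_amplitude_db" in prof.reasons
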