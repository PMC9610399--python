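"""The MFCC chain: framing, windowing, spectra, mel pooling, DCT, padding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pandacall.features import (
    LogMelSpectrum,
    frame_signal,
    hamming_window,
    hz_to_mel,
    inverse_mfcc,
    log_mel,
    logmel_from_segment,
    mel_filterbank,
    mfcc,
    mfcc_from_segment,
    pad_logmel,
    power_spectrum,
)

from conftest import make_segment


def brute_force_frame_count(n_samples: int, n_fft: int, hop: int) -> int:
    """Enumerate valid start positions on the reflect-padded signal."""
    padded = n_samples + 2 * (n_fft // 2)
    return sum(1 for start in range(0, padded, hop) if start + n_fft <= padded)


class TestFraming:
    def test_two_second_segment_gives_173_frames(self):
        fm = frame_signal(np.zeros(88_200), 1024, 512, centered=True)
        assert fm.n_frames == 173

    def test_single_fft_window_gives_three_frames(self):
        assert frame_signal(np.zeros(1024), 1024, 512, True).n_frames == 3

    def test_hop_equal_to_length_gives_two_frames(self):
        assert frame_signal(np.zeros(512), 1024, 512, True).n_frames == 2

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            frame_signal(np.array([]), 1024, 512, True)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=600, max_value=120_000))
    def test_count_matches_enumeration_and_formula(self, n):
        fm = frame_signal(np.zeros(n), 1024, 512, centered=True)
        assert fm.n_frames == brute_force_frame_count(n, 1024, 512)
        assert fm.n_frames == 1 + n // 512

    def test_frames_tile_the_signal(self):
        x = np.arange(4096, dtype=float)
        fm = frame_signal(x, 1024, 512, centered=True)
        # center sample of frame t is x[t*hop] (after removing the pad offset)
        for t in range(1, fm.n_frames - 1):
            assert fm.frames[t, 512] == x[t * 512]


class TestHammingWindow:
    def test_endpoints_and_midpoint(self):
        w = hamming_window(1025)
        assert w[0] == pytest.approx(0.08)
        assert w[-1] == pytest.approx(0.08)
        assert w[512] == pytest.approx(1.0)

    def test_symmetry(self):
        w = hamming_window(1024)
        assert np.allclose(w, w[::-1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hamming_window(1)


class TestPowerSpectrum:
    def test_zero_frame_gives_zero_row(self):
        out = power_spectrum(np.zeros((3, 1024)))
        assert out.shape == (3, 513)
        assert np.all(out == 0)

    def test_bin_frequency_sinusoid_peaks_at_its_bin(self):
        k, n_fft, sr = 40, 1024, 44_100
        t = np.arange(n_fft)
        frame = np.sin(2 * np.pi * k * t / n_fft)
        out = power_spectrum(frame[None, :])
        assert out[0].argmax() == k
        # cross-check height against the direct DFT formula |X_k| = n/2
        assert out[0, k] == pytest.approx((n_fft / 2) ** 2, rel=1e-9)

    def test_parseval(self):
        gen = np.random.default_rng(3)
        frame = gen.normal(0, 1, 1024) * hamming_window(1024)
        full = np.abs(np.fft.fft(frame)) ** 2
        assert full.sum() == pytest.approx(1024 * np.sum(frame**2), rel=1e-9)
        half = power_spectrum(frame[None, :])[0]
        two_sided = 2 * half.sum() - half[0] - half[-1]
        assert two_sided == pytest.approx(1024 * np.sum(frame**2), rel=1e-6)


class TestMelFilterbank:
    def test_shape_and_default_band(self):
        fb = mel_filterbank()
        assert fb.weights.shape == (64, 513)
        assert fb.f_max == pytest.approx(22_050.0)

    def test_mel_map_closed_form(self):
        assert hz_to_mel(700.0) == pytest.approx(2595.0 * np.log10(2.0))
        assert hz_to_mel(0.0) == 0.0

    def test_rows_are_single_triangular_bumps(self):
        fb = mel_filterbank()
        for row in fb.weights:
            assert np.all(row >= 0)
            support = np.flatnonzero(row > 0)
            assert support.size > 0
            peak = row.argmax()
            assert np.all(np.diff(row[support[0] : peak + 1]) >= -1e-12)  # rises
            assert np.all(np.diff(row[peak : support[-1] + 1]) <= 1e-12)  # falls

    def test_band_fully_covered(self):
        fb = mel_filterbank()
        bin_hz = np.fft.rfftfreq(1024, 1 / 44_100)
        interior = (bin_hz > fb.weights.shape[0] / 64) & (bin_hz < 22_050 * 0.98)
        coverage = fb.weights.sum(axis=0)
        first_center = 22_050 / 65  # below the first triangle there is no weight
        assert np.all(coverage[(bin_hz > 340) & interior] > 0)
        assert first_center > 300  # sanity on the gap bound used above

    def test_peak_normalized_at_center(self):
        fb = mel_filterbank()
        # the analytic triangle reaches exactly 1 at its own center frequency
        for m in range(fb.n_mels):
            assert fb.response(m, fb.centers_hz[m + 1]) == pytest.approx(1.0)
        # and the discrete grid never exceeds that peak
        assert np.all(fb.weights <= 1.0 + 1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(f_min=5000, f_max=1000)


class TestLogMel:
    def test_zero_power_clamps_to_log_floor(self):
        fb = mel_filterbank()
        spec = log_mel(np.zeros((5, 513)), fb, floor=1e-10)
        assert np.allclose(spec.values, np.log(1e-10))

    def test_doubling_power_adds_log2(self):
        fb = mel_filterbank()
        power = np.random.default_rng(0).uniform(0.5, 2.0, (4, 513))
        a = log_mel(power, fb).values
        b = log_mel(2 * power, fb).values
        assert np.allclose(b - a, np.log(2.0), atol=1e-9)

    def test_white_noise_gives_finite_row(self):
        fb = mel_filterbank()
        frame = np.random.default_rng(1).normal(0, 1, 1024)
        power = power_spectrum(frame[None, :])
        vals = log_mel(power, fb).values
        assert vals.shape == (1, 64)
        assert np.all(np.isfinite(vals))
        # oracle: plain matrix multiply against the filterbank
        assert np.allclose(vals, np.log(np.maximum(power @ fb.weights.T, 1e-10)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            log_mel(np.zeros((2, 100)), mel_filterbank())


class TestPadLogmel:
    def test_full_input_unchanged(self):
        spec = LogMelSpectrum(values=np.ones((173, 64)))
        assert pad_logmel(spec) is spec

    def test_padding_rows_appended_zero(self):
        spec = LogMelSpectrum(values=np.ones((100, 64)))
        out = pad_logmel(spec)
        assert out.values.shape == (173, 64)
        assert np.all(out.values[:100] == 1.0)
        assert np.all(out.values[100:] == 0.0)
        assert out.effective_frames == 100

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            pad_logmel(LogMelSpectrum(values=np.ones((200, 64))))


class TestMFCC:
    def test_full_segment_gives_canonical_shape(self):
        m = mfcc_from_segment(make_segment())
        assert m.shape == (173, 64)

    def test_dct_round_trip(self):
        vals = np.random.default_rng(2).normal(0, 1, (10, 64))
        spec = LogMelSpectrum(values=vals)
        back = inverse_mfcc(mfcc(spec))
        assert np.allclose(back, vals, atol=1e-9)

    def test_constant_frame_energy_in_dc_coefficient(self):
        c = 3.7
        spec = LogMelSpectrum(values=np.full((1, 64), c))
        m = mfcc(spec).values[0]
        assert m[0] == pytest.approx(c * np.sqrt(64))
        assert np.allclose(m[1:], 0.0, atol=1e-9)

    def test_too_many_coeffs_rejected(self):
        with pytest.raises(ValueError):
            mfcc(LogMelSpectrum(values=np.zeros((3, 64))), n_coeffs=65)


class TestEndToEnd:
    @pytest.mark.parametrize("n_samples", [88_200, 60_000, 30_000, 8_820])
    def test_any_segment_length_maps_to_173_by_64(self, n_samples):
        seg = make_segment(n_samples=n_samples)
        spec = logmel_from_segment(seg)
        assert spec.values.shape == (173, 64)
        assert spec.effective_frames == 1 + n_samples // 512
        if n_samples < 88_200:
            assert np.all(spec.values[spec.effective_frames :] == 0.0)

    def test_filterbank_application_is_row_independent(self):
        fb = mel_filterbank()
        power = np.random.default_rng(4).uniform(0, 1, (20, 513))
        perm = np.random.default_rng(5).permutation(20)
        direct = log_mel(power, fb).values[perm]
        permuted_first = log_mel(power[perm], fb).values
        assert np.array_equal(direct, permuted_first)
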