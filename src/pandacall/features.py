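"""Log-mel spectra and MFCC matrices.

The feature chain is the classical one: frame the waveform (n_fft=1024,
hop=512, centered with reflect padding), apply a Hamming window, take the
magnitude-squared FFT, pool the power spectrum through 64 triangular mel
filters, take the log, and finish with an orthonormal DCT-II across the mel
axis.  All 64 cepstral coefficients are kept, so the DCT is invertible and a
2-second segment at 44,100 Hz always maps to a 173 x 64 matrix — the
classifier's input shape (173, 64, 1).

Segments shorter than 2 s are zero-padded *here*, in the log-mel domain:
rows of zeros are appended after the last real frame until the matrix has
``TARGET_FRAMES`` rows.  ``effective_frames`` records where real data ends so
augmentation can stay off the padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dct, idct

from .audio_io import CANONICAL_RATE
from .preprocess import CallSegment

N_FFT = 1024
HOP_LENGTH = 512
N_MELS = 64
TARGET_FRAMES = 173  # frames of a full 2-s segment: 1 + 88200 // 512
LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class FeatureConfig:
    sample_rate: int = CANONICAL_RATE
    n_fft: int = N_FFT
    hop_length: int = HOP_LENGTH
    n_mels: int = N_MELS
    f_min: float = 0.0
    f_max: float | None = None  # None -> Nyquist
    log_floor: float = LOG_FLOOR
    target_frames: int = TARGET_FRAMES


@dataclass
class FrameMatrix:
    frames: np.ndarray  # (n_frames, frame_length)
    frame_length: int
    hop: int
    centered: bool

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MelFilterbank:
    weights: np.ndarray  # (n_mels, n_fft//2 + 1), nonnegative
    sample_rate: int
    n_fft: int
    f_min: float
    f_max: float
    centers_hz: np.ndarray | None = None  # n_mels + 2 edge/center frequencies

    @property
    def n_mels(self) -> int:
        return self.weights.shape[0]

    def response(self, m: int, freq_hz: float) -> float:
        """Analytic triangle m evaluated at an arbitrary frequency (peak 1)."""
        lo, c, hi = self.centers_hz[m], self.centers_hz[m + 1], self.centers_hz[m + 2]
        up = (freq_hz - lo) / (c - lo)
        down = (hi - freq_hz) / (hi - c)
        return float(max(0.0, min(up, down)))


@dataclass
class LogMelSpectrum:
    values: np.ndarray  # (n_frames, n_mels), natural-log energy
    sample_rate: int = CANONICAL_RATE
    n_fft: int = N_FFT
    hop_length: int = HOP_LENGTH
    #: rows >= effective_frames are padding (all-zero), not observed signal
    effective_frames: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.effective_frames < 0:
            self.effective_frames = self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_mels(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "LogMelSpectrum":
        return replace(self, values=self.values.copy())


@dataclass
class MFCCMatrix:
    values: np.ndarray  # (n_frames, n_coeffs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def frame_signal(
    samples: np.ndarray, n_fft: int = N_FFT, hop: int = HOP_LENGTH, centered: bool = True
) -> FrameMatrix:
    """Slice a 1-D signal into overlapping frames.

    Centered framing reflect-pads n_fft//2 samples at each end so frame t is
    centered on sample t*hop; the frame count is then 1 + floor(L / hop).
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("frame_signal expects a 1-D mono signal")
    if x.size == 0:
        raise ValueError("cannot frame an empty signal")
    if n_fft <= 0 or not 0 < hop <= n_fft:
        raise ValueError(f"invalid framing parameters n_fft={n_fft}, hop={hop}")
    if centered:
        pad = n_fft // 2
        if x.size < 2:  # reflect needs at least 2 samples
            x = np.pad(x, (0, 2 - x.size))
        x = np.pad(x, pad, mode="reflect")
        n_frames = 1 + (x.size - n_fft) // hop
    else:
        if x.size < n_fft:
            raise ValueError("signal shorter than one frame (uncentered mode)")
        n_frames = 1 + (x.size - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameMatrix(frames=x[idx], frame_length=n_fft, hop=hop, centered=centered)


def hamming_window(n: int) -> np.ndarray:
    """w[k] = 0.54 - 0.46 cos(2*pi*k / (n-1)), the classic Hamming taper."""
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    k = np.arange(n)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (n - 1))


def power_spectrum(frames: FrameMatrix | np.ndarray) -> np.ndarray:
    """|FFT|^2 of each (windowed) frame, keeping bins 0 .. n_fft/2."""
    mat = frames.frames if isinstance(frames, FrameMatrix) else np.asarray(frames)
    return np.abs(np.fft.rfft(mat, axis=-1)) ** 2


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    sample_rate: int = CANONICAL_RATE,
    n_fft: int = N_FFT,
    n_mels: int = N_MELS,
    f_min: float = 0.0,
    f_max: float | None = None,
) -> MelFilterbank:
    """Peak-normalized triangular filters with centers equispaced in mel.

    Filter m rises linearly (in Hz) from center m-1 to 1 at center m and
    falls to 0 at center m+1; centers use the HTK mel map
    mel(f) = 2595 log10(1 + f/700).
    """
    if f_max is None:
        f_max = sample_rate / 2.0
    if not 0.0 <= f_min < f_max <= sample_rate / 2.0:
        raise ValueError(f"invalid mel band [{f_min}, {f_max}] for rate {sample_rate}")
    centers_mel = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_mels + 2)
    centers_hz = np.asarray(mel_to_hz(centers_mel))
    bin_hz = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    lower, center, upper = centers_hz[:-2], centers_hz[1:-1], centers_hz[2:]
    up = (bin_hz[None, :] - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - bin_hz[None, :]) / (upper - center)[:, None]
    weights = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(
        weights=weights, sample_rate=sample_rate, n_fft=n_fft, f_min=f_min,
        f_max=float(f_max), centers_hz=centers_hz,
    )


def log_mel(
    power: np.ndarray, fb: MelFilterbank, floor: float = LOG_FLOOR, **spec_kwargs
) -> LogMelSpectrum:
    """Natural log of mel-pooled power, clamped below at ``floor``."""
    power = np.asarray(power, dtype=np.float64)
    if power.shape[-1] != fb.weights.shape[1]:
        raise ValueError(
            f"power spectrum has {power.shape[-1]} bins, filterbank expects "
            f"{fb.weights.shape[1]}"
        )
    mel_energy = power @ fb.weights.T
    values = np.log(np.maximum(mel_energy, floor))
    return LogMelSpectrum(values=values, sample_rate=fb.sample_rate, n_fft=fb.n_fft, **spec_kwargs)


def pad_logmel(spec: LogMelSpectrum, target_frames: int = TARGET_FRAMES) -> LogMelSpectrum:
    """Append all-zero rows after the last real frame up to ``target_frames``."""
    n = spec.n_frames
    if n > target_frames:
        raise ValueError(f"spectrum has {n} frames, more than target {target_frames}; segment first")
    if n == target_frames:
        return spec
    padded = np.zeros((target_frames, spec.n_mels), dtype=spec.values.dtype)
    padded[:n] = spec.values
    return replace(spec, values=padded, effective_frames=min(spec.effective_frames, n))


def mfcc(spec: LogMelSpectrum, n_coeffs: int = N_MELS) -> MFCCMatrix:
    """Orthonormal DCT-II across the mel axis, keeping the first n_coeffs."""
    if n_coeffs > spec.n_mels:
        raise ValueError(f"n_coeffs={n_coeffs} exceeds n_mels={spec.n_mels}")
    coeffs = dct(spec.values, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    return MFCCMatrix(values=coeffs)


def inverse_mfcc(m: MFCCMatrix, n_mels: int = N_MELS) -> np.ndarray:
    """Invert a full-coefficient MFCC back to log-mel values (test surface)."""
    if m.values.shape[1] != n_mels:
        raise ValueError("inverse requires the full coefficient set")
    return idct(m.values, type=2, norm="ortho", axis=1)


def logmel_from_segment(segment: CallSegment, cfg: FeatureConfig = FeatureConfig()) -> LogMelSpectrum:
    """Waveform -> padded 173 x 64 log-mel spectrum for one call segment."""
    if segment.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"segment rate {segment.sample_rate} != feature rate {cfg.sample_rate}"
        )
    frames = frame_signal(segment.samples, cfg.n_fft, cfg.hop_length, centered=True)
    windowed = frames.frames * hamming_window(cfg.n_fft)[None, :]
    power = power_spectrum(windowed)
    fb = _cached_filterbank(cfg)
    spec = log_mel(power, fb, floor=cfg.log_floor)
    spec.hop_length = cfg.hop_length
    return pad_logmel(spec, cfg.target_frames)


def mfcc_from_segment(segment: CallSegment, cfg: FeatureConfig = FeatureConfig()) -> MFCCMatrix:
    """Waveform -> 173 x 64 MFCC matrix (the network input)."""
    return mfcc(logmel_from_segment(segment, cfg), n_coeffs=cfg.n_mels)


_FB_CACHE: dict[tuple, MelFilterbank] = {}


def _cached_filterbank(cfg: FeatureConfig) -> MelFilterbank:
    key = (cfg.sample_rate, cfg.n_fft, cfg.n_mels, cfg.f_min, cfg.f_max)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(
            cfg.sample_rate, cfg.n_fft, cfg.n_mels, cfg.f_min, cfg.f_max
        )
    return _FB_CACHE[key]
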