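"""PCM WAV ingestion, channel mixdown and resampling.

Field recordings arrive as mono or stereo RIFF/WAVE files at whatever rate the
recorder used (44.1, 48 or 192 kHz are typical).  Everything downstream of
this module works on mono float waveforms in [-1, 1] at a single canonical
rate, 44,100 Hz.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 44_100

#: full-scale divisor per integer PCM dtype, mapping the most negative code
#: to exactly -1.0
_INT_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,  # scipy widens 24-bit PCM into int32
}


@dataclass
class AudioClip:
    """A sampled waveform: ``samples`` is (n,) mono or (n, channels)."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError(f"empty audio clip ({self.source_id!r})")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite amplitude values")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM/float WAV file, normalizing integer codes to [-1, 1].

    8/16/24/32-bit integer and 32/64-bit float encodings are accepted; the
    header's sample rate and channel count are preserved as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise ValueError(f"unsupported or non-PCM WAV encoding in {path}: {exc}") from exc
    except Exception as exc:  # truncated / malformed RIFF
        raise OSError(f"unreadable WAV file {path}: {exc}") from exc

    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype in (np.float32, np.float64):
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(path: str | Path, clip: AudioClip, bit_depth: int = 16) -> None:
    """Write ``clip`` as integer PCM (8/16/24/32 bits) or 32-bit float."""
    path = Path(path)
    x = np.clip(clip.samples, -1.0, 1.0)
    if bit_depth in (16, 32):
        full = 2 ** (bit_depth - 1)
        dtype = np.int16 if bit_depth == 16 else np.int32
        data = np.clip(np.round(x * full), -full, full - 1).astype(dtype)
        wavfile.write(str(path), clip.sample_rate, data)
    elif bit_depth == 8:
        data = np.clip(np.round(x * 128.0) + 128.0, 0, 255).astype(np.uint8)
        wavfile.write(str(path), clip.sample_rate, data)
    elif bit_depth == 24:
        _write_wav_24bit(path, x, clip.sample_rate)
    elif bit_depth == 0:  # float32 passthrough
        wavfile.write(str(path), clip.sample_rate, x.astype(np.float32))
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}")


def _write_wav_24bit(path: Path, x: np.ndarray, rate: int) -> None:
    codes = np.clip(np.round(x * 2.0**23), -(2**23), 2**23 - 1).astype("<i4")
    if codes.ndim == 1:
        codes = codes[:, None]
    raw = codes.view(np.uint8).reshape(codes.shape[0], codes.shape[1], 4)
    frames = raw[:, :, :3].tobytes()  # little-endian: low 3 bytes carry the code
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(codes.shape[1])
        fh.setsampwidth(3)
        fh.setframerate(rate)
        fh.writeframes(frames)


def to_mono(clip: AudioClip) -> AudioClip:
    """Average channels sample-wise; a mono clip is returned unchanged."""
    if clip.n_channels == 1:
        return clip
    return replace(clip, samples=clip.samples.mean(axis=1))


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Band-limited rational-factor (polyphase) resampling to ``target_rate``."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    ratio = Fraction(target_rate, clip.sample_rate)
    out = resample_poly(clip.samples, ratio.numerator, ratio.denominator, axis=0)
    # polyphase output length is ceil(n*up/down); trim/pad to the rounded length
    n_target = round(clip.n_samples * target_rate / clip.sample_rate)
    if out.shape[0] > n_target:
        out = out[:n_target]
    elif out.shape[0] < n_target:
        pad = [(0, n_target - out.shape[0])] + [(0, 0)] * (out.ndim - 1)
        out = np.pad(out, pad)
    return replace(clip, samples=out, sample_rate=int(target_rate))


# ---------------------------------------------------------------------------
# clip manifests

MANIFEST_COLUMNS = ["clip_path", "individual_id", "age_group", "sex"]
AGE_GROUPS = ("juvenile", "adult")
SEXES = ("female", "male")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a clip manifest CSV (clip path plus labels)."""
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    bad_age = set(df["age_group"]) - set(AGE_GROUPS)
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_age or bad_sex:
        raise ValueError(f"manifest {path} has invalid labels: {bad_age | bad_sex}")
    return df


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
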