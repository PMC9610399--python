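"""Segmentation of call clips and background-noise mixing.

Call clips are cut into non-overlapping 2-second segments, the unit on which
classification operates.  A trailing segment shorter than 2 s is kept and
flagged; the actual padding happens later, in the log-mel domain, so the
feature matrix of every segment ends up the same size.  Tails shorter than
``min_tail_seconds`` (default 0.2 s) are discarded as recording artifacts.

``mix_background`` implements the enclosure-noise equalization step: clean
recordings (cub calls, in the study population this emulates) get a random
excerpt of the noisier group's background mixed in at a target SNR, so the
classifier cannot key on recording conditions instead of the voice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .audio_io import CANONICAL_RATE, AudioClip

SEGMENT_SECONDS = 2.0
MIN_TAIL_SECONDS = 0.2


@dataclass
class CallSegment:
    """A mono waveform of at most 2 s at 44,100 Hz plus its labels."""

    samples: np.ndarray
    individual_id: str
    age_group: str
    sex: str
    source_clip: str
    segment_index: int
    needs_padding: bool
    sample_rate: int = CANONICAL_RATE

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def segment_id(self) -> str:
        return f"{self.source_clip}#{self.segment_index}"

    def label(self, task: str) -> str:
        if task == "age":
            return self.age_group
        if task == "sex":
            return self.sex
        raise ValueError(f"unknown task {task!r} (expected 'age' or 'sex')")


def segment_clip(
    clip: AudioClip,
    individual_id: str,
    age_group: str,
    sex: str,
    seg_seconds: float = SEGMENT_SECONDS,
    min_tail_seconds: float = MIN_TAIL_SECONDS,
) -> list[CallSegment]:
    """Cut a mono clip into non-overlapping fixed-duration segments.

    Returns ``ceil(duration / seg_seconds)`` segments; only the final one may
    be short, and it carries ``needs_padding=True``.  Concatenating the
    returned segments reproduces the clip exactly, except that a final tail
    shorter than ``min_tail_seconds`` is dropped.
    """
    if clip.n_channels != 1:
        raise ValueError("segment_clip expects a mono clip; call to_mono first")
    if clip.n_samples == 0:
        raise ValueError("cannot segment an empty clip")
    seg_len = int(round(seg_seconds * clip.sample_rate))
    min_len = int(round(min_tail_seconds * clip.sample_rate))
    x = clip.samples
    segments: list[CallSegment] = []
    for idx in range(math.ceil(x.shape[0] / seg_len)):
        chunk = x[idx * seg_len : (idx + 1) * seg_len]
        if chunk.shape[0] < seg_len and chunk.shape[0] < min_len:
            break  # drop sub-floor tail
        segments.append(
            CallSegment(
                samples=chunk,
                individual_id=individual_id,
                age_group=age_group,
                sex=sex,
                source_clip=clip.source_id,
                segment_index=idx,
                needs_padding=chunk.shape[0] < seg_len,
                sample_rate=clip.sample_rate,
            )
        )
    return segments


def mix_background(
    segment: CallSegment,
    noise: AudioClip,
    snr_db: float,
    rng: np.random.Generator,
) -> CallSegment:
    """Add a random contiguous noise excerpt at a prescribed signal/noise ratio.

    The gain g satisfies 10*log10(P_signal / P_noise_scaled) = snr_db, with P
    the mean-square power.  ``snr_db = inf`` returns the segment unchanged.
    Labels, length and padding flag are untouched.
    """
    if noise.n_channels != 1 or noise.sample_rate != segment.sample_rate:
        raise ValueError("noise must be mono at the segment's sample rate")
    if noise.n_samples < segment.n_samples:
        raise ValueError(
            f"noise ({noise.n_samples} samples) shorter than segment ({segment.n_samples})"
        )
    if math.isinf(snr_db) and snr_db > 0:
        return segment
    start = int(rng.integers(0, noise.n_samples - segment.n_samples + 1))
    excerpt = noise.samples[start : start + segment.n_samples]
    p_noise = float(np.mean(excerpt**2))
    if p_noise <= 0.0:
        raise ValueError("background noise excerpt has zero power")
    p_signal = float(np.mean(segment.samples**2))
    gain = math.sqrt(p_signal / (p_noise * 10.0 ** (snr_db / 10.0)))
    return replace(segment, samples=segment.samples + gain * excerpt)


def segment_manifest(segments: list[CallSegment], hop: int = 512) -> pd.DataFrame:
    """Tabulate segments: clip-manifest labels plus per-segment bookkeeping.

    ``effective_frames`` is the centered-framing frame count of the raw
    (unpadded) segment, 1 + floor(n_samples / hop).
    """
    return pd.DataFrame(
        {
            "source_clip": [s.source_clip for s in segments],
            "individual_id": [s.individual_id for s in segments],
            "age_group": [s.age_group for s in segments],
            "sex": [s.sex for s in segments],
            "segment_index": [s.segment_index for s in segments],
            "needs_padding": [s.needs_padding for s in segments],
            "effective_frames": [1 + s.n_samples // hop for s in segments],
        }
    )
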