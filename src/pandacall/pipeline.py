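"""Corpus preparation: labelled clips -> per-segment log-mel features.

This is the glue between ingestion and the experiment harness.  A corpus is a
list of :class:`FeatureExample` — one 173 x 64 log-mel spectrum per 2-second
call segment, tagged with the caller's identity and labels.  Keeping features
in the log-mel domain (DCT deferred) lets augmentation operate in
SpecAugment's native domain; the MFCC transform is applied just before the
classifier sees the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import audio_io
from .audio_io import CANONICAL_RATE, AudioClip
from .features import FeatureConfig, LogMelSpectrum, logmel_from_segment, mfcc
from .preprocess import CallSegment, mix_background, segment_clip

DEFAULT_MIX_SNR_DB = 10.0


@dataclass
class FeatureExample:
    """One call segment's log-mel features plus its labels and provenance."""

    logmel: LogMelSpectrum
    individual_id: str
    age_group: str
    sex: str
    segment_id: str
    augmented: bool = False

    def label(self, task: str) -> str:
        if task == "age":
            return self.age_group
        if task == "sex":
            return self.sex
        raise ValueError(f"unknown task {task!r} (expected 'age' or 'sex')")

    def with_logmel(self, logmel: LogMelSpectrum, augmented: bool = True) -> "FeatureExample":
        return replace(self, logmel=logmel, augmented=augmented)


def segments_from_clip(
    clip: AudioClip,
    individual_id: str,
    age_group: str,
    sex: str,
    target_rate: int = CANONICAL_RATE,
) -> list[CallSegment]:
    """Mono-mix, resample to the canonical rate, and cut into 2-s segments."""
    clip = audio_io.to_mono(clip)
    clip = audio_io.resample(clip, target_rate)
    return segment_clip(clip, individual_id, age_group, sex)


def prepare_examples(
    segments: list[CallSegment],
    cfg: FeatureConfig = FeatureConfig(),
    noise_pool: list[AudioClip] | None = None,
    mix_into_age_group: str | None = None,
    mix_snr_db: float = DEFAULT_MIX_SNR_DB,
    rng: np.random.Generator | None = None,
) -> list[FeatureExample]:
    """Featurize segments, optionally equalizing background noise first.

    When ``noise_pool`` is given, segments get a random excerpt from a random
    pool clip mixed in at ``mix_snr_db`` — the guard against the classifier
    learning recording conditions (clean cub enclosures vs. noisy adult ones)
    instead of voices.  By default the mixing is label-blind (every segment,
    same SNR): mixing the shared background floor into everything compresses
    a group-dependent SNR gap without itself becoming a class cue.  Passing
    ``mix_into_age_group="juvenile"`` restricts mixing to one age group
    (noise added only to the clean-enclosure recordings); note that any
    label-conditional preprocessing can leak labels into the features.
    """
    if noise_pool is not None and rng is None:
        raise ValueError("noise mixing needs an rng for excerpt selection")
    out: list[FeatureExample] = []
    for seg in segments:
        if noise_pool is not None and mix_into_age_group in (None, seg.age_group):
            noise = noise_pool[int(rng.integers(0, len(noise_pool)))]
            seg = mix_background(seg, noise, snr_db=mix_snr_db, rng=rng)
        out.append(
            FeatureExample(
                logmel=logmel_from_segment(seg, cfg),
                individual_id=seg.individual_id,
                age_group=seg.age_group,
                sex=seg.sex,
                segment_id=seg.segment_id,
            )
        )
    return out


def corpus_from_manifest(
    manifest_path: str | Path,
    cfg: FeatureConfig = FeatureConfig(),
    noise_dir: str | Path | None = None,
    mix_into_age_group: str | None = None,
    mix_snr_db: float = DEFAULT_MIX_SNR_DB,
    rng: np.random.Generator | None = None,
) -> list[FeatureExample]:
    """Read a clip manifest CSV and featurize every clip it lists.

    ``clip_path`` entries are resolved relative to the manifest's directory.
    ``noise_dir``, if given, is a directory of background-only WAVs used for
    noise equalization of juvenile clips.
    """
    manifest_path = Path(manifest_path)
    df = audio_io.read_manifest(manifest_path)
    root = manifest_path.parent
    noise_pool = None
    if noise_dir is not None:
        noise_files = sorted(Path(noise_dir).glob("*.wav"))
        if not noise_files:
            raise FileNotFoundError(f"no WAV files in noise directory {noise_dir}")
        noise_pool = [
            audio_io.resample(audio_io.to_mono(audio_io.read_wav(p)), cfg.sample_rate)
            for p in noise_files
        ]
    segments: list[CallSegment] = []
    for row in df.itertuples(index=False):
        clip = audio_io.read_wav(root / row.clip_path)
        segments.extend(
            segments_from_clip(clip, str(row.individual_id), row.age_group, row.sex,
                               target_rate=cfg.sample_rate)
        )
    return prepare_examples(
        segments, cfg, noise_pool=noise_pool, mix_into_age_group=mix_into_age_group,
        mix_snr_db=mix_snr_db, rng=rng,
    )


def mfcc_array(examples: list[FeatureExample], n_coeffs: int | None = None) -> np.ndarray:
    """Stack examples into the (N, 1, frames, coeffs) array the network eats."""
    if not examples:
        raise ValueError("empty example list")
    n_coeffs = n_coeffs or examples[0].logmel.n_mels
    mats = [mfcc(ex.logmel, n_coeffs=n_coeffs).values for ex in examples]
    return np.stack(mats).astype(np.float32)[:, None, :, :]


def label_array(examples: list[FeatureExample], task: str, positive_class: str) -> np.ndarray:
    """Binary targets: 1 for the task's positive class, 0 otherwise."""
    return np.array([1 if ex.label(task) == positive_class else 0 for ex in examples])


# feature caches: portable NPZ keyed by segment id ------------------------------


def save_feature_cache(path: str | Path, examples: list[FeatureExample]) -> None:
    arrays = {"__ids__": np.array([ex.segment_id for ex in examples])}
    meta = {
        "individual_id": np.array([ex.individual_id for ex in examples]),
        "age_group": np.array([ex.age_group for ex in examples]),
        "sex": np.array([ex.sex for ex in examples]),
        "effective_frames": np.array([ex.logmel.effective_frames for ex in examples]),
    }
    arrays.update(meta)
    arrays["logmel"] = np.stack([ex.logmel.values for ex in examples]).astype(np.float32)
    np.savez_compressed(path, **arrays)


def load_feature_cache(path: str | Path) -> list[FeatureExample]:
    with np.load(path, allow_pickle=False) as data:
        ids = data["__ids__"]
        lm = data["logmel"].astype(np.float64)
        eff = data["effective_frames"]
        return [
            FeatureExample(
                logmel=LogMelSpectrum(values=lm[i], effective_frames=int(eff[i])),
                individual_id=str(data["individual_id"][i]),
                age_group=str(data["age_group"][i]),
                sex=str(data["sex"][i]),
                segment_id=str(ids[i]),
            )
            for i in range(len(ids))
        ]
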