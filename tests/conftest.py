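"""Shared fixtures: synthetic corpora and small reusable audio objects.

The two featurized corpora (planted structure at separation 1, and the
separation-0 null) are session-scoped because generating and featurizing
~800 calls takes tens of seconds; every experiment-level test shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from pandacall.audio_io import AudioClip
from pandacall.pipeline import FeatureExample, prepare_examples, segments_from_clip
from pandacall.preprocess import CallSegment
from pandacall.synthetic_data import PopulationSpec, background_pool, generate_calls

CORPUS_SEED = 42


def build_corpus(separation: float, seed: int = CORPUS_SEED) -> list[FeatureExample]:
    spec = PopulationSpec(separation=separation)
    rng = np.random.default_rng(seed)
    segments = []
    for profile, clip in generate_calls(spec, rng):
        segments.extend(
            segments_from_clip(clip, profile.individual_id, profile.age_group, profile.sex)
        )
    return prepare_examples(segments, noise_pool=background_pool(spec, rng), rng=rng)


@pytest.fixture(scope="session")
def separated_corpus() -> list[FeatureExample]:
    """Featurized corpus with fully separated class acoustics."""
    return build_corpus(separation=1.0)


@pytest.fixture(scope="session")
def null_corpus() -> list[FeatureExample]:
    """Featurized corpus with no class-dependent acoustics at all."""
    return build_corpus(separation=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tone_clip() -> AudioClip:
    """One second of a 1 kHz tone at 48 kHz, stereo."""
    t = np.arange(48_000) / 48_000
    x = 0.5 * np.sin(2 * np.pi * 1000.0 * t)
    return AudioClip(samples=np.stack([x, x], axis=1), sample_rate=48_000, source_id="tone")


def make_segment(
    n_samples: int = 88_200,
    seed: int = 0,
    individual_id: str = "indA",
    age_group: str = "adult",
    sex: str = "female",
) -> CallSegment:
    gen = np.random.default_rng(seed)
    return CallSegment(
        samples=gen.normal(0.0, 0.1, n_samples),
        individual_id=individual_id,
        age_group=age_group,
        sex=sex,
        source_clip=f"{individual_id}_clip",
        segment_index=0,
        needs_padding=n_samples < 88_200,
    )
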