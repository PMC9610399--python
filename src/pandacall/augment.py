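"""Training-data expansion: Gaussian noise, SpecAugment masks, class balancing.

All three operators act on padded 173 x 64 log-mel spectra and respect the
padding boundary: Gaussian noise is only added to real (non-padded) frames,
time masks are drawn inside the real-frame region, and frequency masks zero
whole columns (padding rows are zero already).  The DCT to MFCC happens after
augmentation.

``balance_dataset`` applies the per-class replication factors used to even
out the study population's imbalance: each original of class c gains r(c)
independently augmented variants (originals retained), so a class with 6
variants per original ends up at 7x its raw count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import LogMelSpectrum
from .pipeline import FeatureExample

#: per-class variant counts: males x6 to meet the female count, juveniles x2,
#: adults x1, females x0
DEFAULT_REPLICATION = {"male": 6, "female": 0, "juvenile": 2, "adult": 1}


@dataclass(frozen=True)
class AugmentationPolicy:
    """Knobs for one augmentation pass; widths in mel bins / frames."""

    gaussian_sigma_rel: float = 0.1  # x the spectrum's own std over real frames
    n_freq_masks: int = 2
    max_freq_width: int = 8
    n_time_masks: int = 1
    max_time_width: int = 20
    replication: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATION))

    def __post_init__(self) -> None:
        for name in ("n_freq_masks", "max_freq_width", "n_time_masks", "max_time_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.replication.values()):
            raise ValueError("replication factors must be >= 0")


def add_gaussian_noise(
    spec: LogMelSpectrum, sigma: float, rng: np.random.Generator
) -> LogMelSpectrum:
    """Add i.i.d. N(0, sigma^2) to every non-padded entry."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = spec.copy()
    if sigma > 0:
        eff = spec.effective_frames
        out.values[:eff] += rng.normal(0.0, sigma, size=(eff, spec.n_mels))
    return out


def freq_mask(
    spec: LogMelSpectrum, n_masks: int, max_width: int, rng: np.random.Generator
) -> LogMelSpectrum:
    """Zero ``n_masks`` random column bands of width ~ U{0..max_width}."""
    if max_width > spec.n_mels:
        raise ValueError(f"max_width {max_width} exceeds {spec.n_mels} mel bins")
    out = spec.copy()
    for _ in range(n_masks):
        w = int(rng.integers(0, max_width + 1))
        f0 = int(rng.integers(0, spec.n_mels - w + 1))
        out.values[:, f0 : f0 + w] = 0.0
    return out


def time_mask(
    spec: LogMelSpectrum, n_masks: int, max_width: int, rng: np.random.Generator
) -> LogMelSpectrum:
    """Zero random row bands, drawn entirely inside the non-padded region."""
    eff = spec.effective_frames
    max_width = min(max_width, eff)
    out = spec.copy()
    for _ in range(n_masks):
        w = int(rng.integers(0, max_width + 1))
        t0 = int(rng.integers(0, eff - w + 1))
        out.values[t0 : t0 + w, :] = 0.0
    return out


def augment_spectrum(
    spec: LogMelSpectrum, policy: AugmentationPolicy, rng: np.random.Generator
) -> LogMelSpectrum:
    """One independent augmentation draw: Gaussian noise then both mask types."""
    eff = spec.effective_frames
    sigma = policy.gaussian_sigma_rel * float(np.std(spec.values[:eff]))
    out = add_gaussian_noise(spec, sigma, rng)
    out = freq_mask(out, policy.n_freq_masks, policy.max_freq_width, rng)
    out = time_mask(out, policy.n_time_masks, policy.max_time_width, rng)
    return out


def balance_dataset(
    examples: list[FeatureExample],
    policy: AugmentationPolicy,
    task: str,
    rng: np.random.Generator,
) -> list[FeatureExample]:
    """Expand a training set by the task's per-class replication factors.

    Returns originals plus r(class) fresh augmented variants per original;
    variants keep their parent's labels, individual ID and segment ID (with a
    suffix), so split hygiene checks see them as the same caller.
    """
    out = list(examples)
    for ex in examples:
        cls = ex.label(task)
        if cls not in policy.replication:
            raise KeyError(f"no replication factor for class {cls!r}")
        for k in range(policy.replication[cls]):
            var = ex.with_logmel(augment_spectrum(ex.logmel, policy, rng))
            var.segment_id = f"{ex.segment_id}+aug{k}"
            out.append(var)
    return out
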