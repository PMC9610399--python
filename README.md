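# pandacall

Automatic recognition of giant-panda attributes — **age group** (juvenile
vs. adult) and **sex** — from their vocalizations.

Conservation surveys need the age structure and sex ratio of wild panda
populations, and the traditional field methods (bamboo bite-size analysis,
fecal DNA) are slow, expensive and partial. Panda calls carry this
information: both source features (fundamental frequency) and filter
features (formants) of bleat-like vocalizations differ systematically with
a caller's age, sex and body size. `pandacall` implements a complete
recognizer for that setting, aimed at bioacousticians working with small,
imbalanced call collections:

* **Preprocessing** — mono mixdown, resampling to 44.1 kHz, non-overlapping
  2-s segmentation, and label-blind background-noise equalization so the
  model cannot learn recording conditions instead of voices.
* **Features** — classical MFCCs (n_fft = 1024, hop = 512, 64 mel filters,
  orthonormal DCT-II, all 64 coefficients kept); every segment becomes a
  173 × 64 matrix, short segments zero-padded in the log-mel domain.
* **Classifier** — a compact CNN with Squeeze-and-Excitation channel
  attention (squeeze: per-channel global average; excite: bottleneck MLP
  with sigmoid gates; rescale), trained with Adam (batch 32, lr 1e-3),
  implemented directly on NumPy with tested gradients.
* **Imbalance handling** — SpecAugment-style masking plus Gaussian noise on
  the log-mel spectrum, per-class replication factors (males ×6,
  juveniles ×2, adults ×1), and focal loss
  FL(p_t) = −α_t (1 − p_t)^γ log p_t with a cross-entropy baseline.
* **Evaluation** — individual-exclusive cross-validation: per repetition, 4
  callers are held out, their segments copied/subsampled to exactly 100
  test clips, training subsampled to exactly 540 clips; precision, recall
  and F1 (positive classes: adult, female) reported as mean ± SD over 10
  repetitions, with a pooled-split control and a training-size sweep
  (540→720 by 30).
* **Synthetic corpus** — a seeded source–filter call generator that emulates
  the study population (8 juvenile females, 3 juvenile males, 13 adult
  females, 4 adult males) with per-caller random effects and a `separation`
  knob from null model (0) to fully separated classes (1), so the entire
  pipeline is testable without any recordings.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
import numpy as np
from pandacall import PopulationSpec, run_experiment, test_profile
from pandacall.pipeline import prepare_examples, segments_from_clip
from pandacall.synthetic_data import background_pool, generate_calls

# a synthetic corpus with fully separated class acoustics
spec = PopulationSpec(separation=1.0)
rng = np.random.default_rng(42)
segments = []
for profile, clip in generate_calls(spec, rng):
    segments.extend(segments_from_clip(clip, profile.individual_id,
                                       profile.age_group, profile.sex))
examples = prepare_examples(segments, noise_pool=background_pool(spec, rng), rng=rng)

# individual-exclusive, augmented, focal-loss evaluation of the age task
result = run_experiment("E2C", "age", examples,
                        model_config=test_profile(), n_reps=5, seed=7)
print(result.summary())
```

This prints (light test profile — small model, 20 epochs):

```
E2C / age task (5 repetitions, 540 training clips)
metric          mean      sd
precision     98.31%   3.79%
recall       100.00%   0.00%
f1            99.12%   1.98%
```

Meaning: with the planted age cue fully separated (juvenile calls centered
2.4× higher in F0 than adult calls), a recognizer that never saw the four
held-out individuals still labels their 100 test segments nearly perfectly
across repetitions. On the null corpus (`separation=0.0`) the same pipeline
falls to chance-level F1 — the no-leakage control — and the sex task, whose
formant cue is deliberately weaker, lands in between.

## Command line

```bash
pandacall generate  --seed 1 --out data/                   # synthetic corpus
pandacall featurize --seed 1 --data data/ --out feat.npz   # 2-s MFCC cache
pandacall run   --features feat.npz --arm E2C --task age --seed 1 --out results/
pandacall sweep --features feat.npz --task sex --seed 1 --out results/
```

Arms mirror the evaluation design: `E1` pooled split, `E2A` exclusive,
`E2B` exclusive + augmentation, `E2C` exclusive + augmentation + focal
loss. A YAML config (`--config`) can override the population, features,
augmentation policy, model profile and repetition counts; every output
directory records the resolved config and seeds.

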