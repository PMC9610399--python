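"""Metrics, individual-exclusive splits, and the experiment harness.

The evaluation protocol mirrors a small-population bioacoustic study: per
repetition, four individuals are held out as the test set (so no caller's
segments appear on both sides — the speaker-independent analogue), their
segments are copied or subsampled to exactly 100, and the training pool from
the remaining individuals is subsampled to exactly 540 segments.  Ten seeded
repetitions yield mean +- SD of precision, recall and F1.

Experiment arms:

====  ==================  ============  =============
arm   individual-excl.    augmentation  loss
====  ==================  ============  =============
E1    no (pooled split)   no            cross entropy
E2A   yes                 no            cross entropy
E2B   yes                 yes           cross entropy
E2C   yes                 yes           focal
====  ==================  ============  =============

A training-size sweep (540 to 720 in steps of 30, test individuals fixed
within a repetition) probes how much the small training pool limits the
recognizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, balance_dataset
from .loss import LossFn, alpha_from_counts, make_cross_entropy, make_focal_loss
from .model import ModelConfig, SECallNet, build_model, train
from .pipeline import FeatureExample, label_array, mfcc_array

ARMS = ("E1", "E2A", "E2B", "E2C")
TASKS = ("age", "sex")
#: positive-class convention per task
POSITIVE_CLASS = {"age": "adult", "sex": "female"}
N_TEST_INDIVIDUALS = 4
TEST_SIZE = 100
TRAIN_SIZE = 540
N_REPETITIONS = 10


# --------------------------------------------------------------------------
# confusion counts and the three metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(predicted, true, positive_class) -> ConfusionCounts:
    """Standard 2x2 tally of a binary prediction against the truth."""
    pred = np.asarray(predicted)
    truth = np.asarray(true)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {truth.shape} labels")
    p_pos = pred == positive_class
    t_pos = truth == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p_pos & t_pos)),
        fp=int(np.sum(p_pos & ~t_pos)),
        fn=int(np.sum(~p_pos & t_pos)),
        tn=int(np.sum(~p_pos & ~t_pos)),
    )


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp); 0 when no positive predictions were made."""
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn); 0 when there are no positive samples."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when either is undefined-0."""
    p, r = precision(c), recall(c)
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


# --------------------------------------------------------------------------
# split construction


@dataclass
class SplitPlan:
    repetition_index: int
    mutually_exclusive: bool
    test_individuals: frozenset[str]
    train_individuals: frozenset[str]
    train_indices: np.ndarray  # indices into the example list, len 540
    test_indices: np.ndarray  # len 100, may repeat (copied clips)
    seed: int


def _copy_or_subsample(pool: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin copy a small pool up to ``size``, or subsample a large one."""
    if len(pool) >= size:
        return rng.choice(pool, size=size, replace=False)
    shuffled = rng.permutation(pool)
    reps = int(np.ceil(size / len(shuffled)))
    return np.tile(shuffled, reps)[:size]


def make_splits(
    examples: list[FeatureExample],
    mutually_exclusive: bool = True,
    n_reps: int = N_REPETITIONS,
    rng: np.random.Generator | None = None,
    n_test_individuals: int = N_TEST_INDIVIDUALS,
    test_size: int = TEST_SIZE,
    train_size: int = TRAIN_SIZE,
    seed: int = 0,
) -> list[SplitPlan]:
    """Build one train/test assignment per repetition.

    Exclusive mode holds out ``n_test_individuals`` whole individuals; pooled
    mode (the non-exclusive control) splits segments at random regardless of
    caller.  Test pools are copied/subsampled to ``test_size`` and train
    pools subsampled to ``train_size``.
    """
    rng = rng or np.random.default_rng(seed)
    by_individual: dict[str, list[int]] = {}
    for i, ex in enumerate(examples):
        by_individual.setdefault(ex.individual_id, []).append(i)
    individuals = np.array(sorted(by_individual))
    if mutually_exclusive and len(individuals) <= n_test_individuals:
        raise ValueError(
            f"need more than {n_test_individuals} individuals, have {len(individuals)}"
        )
    plans = []
    for rep in range(n_reps):
        if mutually_exclusive:
            test_ind = rng.choice(individuals, size=n_test_individuals, replace=False)
            train_ind = np.array([i for i in individuals if i not in set(test_ind)])
            test_pool = np.concatenate([by_individual[i] for i in test_ind])
            train_pool = np.concatenate([by_individual[i] for i in train_ind])
        else:
            order = rng.permutation(len(examples))
            test_pool, train_pool = order[:test_size], order[test_size:]
            test_ind = np.unique([examples[i].individual_id for i in test_pool])
            train_ind = np.unique([examples[i].individual_id for i in train_pool])
        if len(train_pool) < train_size:
            raise ValueError(
                f"repetition {rep}: training pool has {len(train_pool)} segments, "
                f"needs {train_size} ({train_size - len(train_pool)} short)"
            )
        plans.append(
            SplitPlan(
                repetition_index=rep,
                mutually_exclusive=mutually_exclusive,
                test_individuals=frozenset(map(str, test_ind)),
                train_individuals=frozenset(map(str, train_ind)),
                # unsorted so any prefix is itself a uniform subsample
                train_indices=rng.choice(train_pool, size=train_size, replace=False),
                test_indices=_copy_or_subsample(np.asarray(test_pool), test_size, rng),
                seed=seed,
            )
        )
    return plans


# --------------------------------------------------------------------------
# results container


@dataclass
class EvalResult:
    arm: str
    task: str
    precisions: np.ndarray
    recalls: np.ndarray
    f1s: np.ndarray
    train_size: int = TRAIN_SIZE

    @property
    def n_reps(self) -> int:
        return len(self.f1s)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = getattr(self, metric + "s")
        return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"{self.arm} / {self.task} task "
            f"({self.n_reps} repetitions, {self.train_size} training clips)",
            f"{'metric':<12}{'mean':>8}{'sd':>8}",
        ]
        for metric in ("precision", "recall", "f1"):
            m, s = self.mean_sd(metric)
            lines.append(f"{metric:<12}{100 * m:>7.2f}%{100 * s:>7.2f}%")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repetition": np.arange(self.n_reps),
                "precision": self.precisions,
                "recall": self.recalls,
                "f1": self.f1s,
            }
        )

    def to_json_summary(self) -> dict:
        out = {"arm": self.arm, "task": self.task, "train_size": self.train_size}
        for metric in ("precision", "recall", "f1"):
            m, s = self.mean_sd(metric)
            out[metric] = {"mean": m, "sd": s}
        return out

    def save(self, directory: str | Path, stem: str | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"{self.arm}_{self.task}_{self.train_size}"
        self.to_frame().to_csv(directory / f"{stem}.csv", index=False)
        (directory / f"{stem}.json").write_text(json.dumps(self.to_json_summary(), indent=2))


# --------------------------------------------------------------------------
# experiment harness


@dataclass(frozen=True)
class ArmSettings:
    mutually_exclusive: bool
    augment: bool
    loss: str


ARM_SETTINGS = {
    "E1": ArmSettings(mutually_exclusive=False, augment=False, loss="cross_entropy"),
    "E2A": ArmSettings(mutually_exclusive=True, augment=False, loss="cross_entropy"),
    "E2B": ArmSettings(mutually_exclusive=True, augment=True, loss="cross_entropy"),
    "E2C": ArmSettings(mutually_exclusive=True, augment=True, loss="focal"),
}


def _make_loss(name: str, y_train: np.ndarray, gamma: float) -> LossFn:
    if name == "focal":
        counts = np.bincount(y_train, minlength=2)
        return make_focal_loss(gamma=gamma, alpha=alpha_from_counts(np.maximum(counts, 1)))
    return make_cross_entropy()


def _run_one_rep(
    examples: list[FeatureExample],
    plan: SplitPlan,
    task: str,
    settings: ArmSettings,
    model_config: ModelConfig,
    policy: AugmentationPolicy,
    focal_gamma: float,
    model_rng: np.random.Generator,
    train_rng: np.random.Generator,
    aug_rng: np.random.Generator,
) -> tuple[float, float, float]:
    train_examples = [examples[i] for i in plan.train_indices]
    test_examples = [examples[i] for i in plan.test_indices]
    if settings.augment:
        train_examples = balance_dataset(train_examples, policy, task, aug_rng)
    positive = POSITIVE_CLASS[task]
    x_train = mfcc_array(train_examples)
    y_train = label_array(train_examples, task, positive)
    x_test = mfcc_array(test_examples)
    y_test = label_array(test_examples, task, positive)
    loss_fn = _make_loss(settings.loss, y_train, focal_gamma)
    model = build_model(model_config, model_rng)
    train(model, x_train, y_train, loss_fn, model_config, rng=train_rng)
    pred = model.predict(x_test)
    c = confusion_counts(pred, y_test, positive_class=1)
    return precision(c), recall(c), f1(c)


def run_experiment(
    arm: str,
    task: str,
    examples: list[FeatureExample],
    model_config: ModelConfig | None = None,
    policy: AugmentationPolicy | None = None,
    n_reps: int = N_REPETITIONS,
    train_size: int = TRAIN_SIZE,
    seed: int = 0,
    focal_gamma: float = 2.0,
) -> EvalResult:
    """Run one experiment arm end to end and return per-repetition metrics.

    The arm fixes the split mode, augmentation, and loss; each repetition
    draws a fresh split, optionally balances the training half, trains a
    freshly initialized classifier, and scores the held-out 100 segments.
    """
    if arm not in ARM_SETTINGS:
        raise ValueError(f"unknown arm {arm!r}; valid arms: {', '.join(ARMS)}")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks: {', '.join(TASKS)}")
    settings = ARM_SETTINGS[arm]
    model_config = model_config or ModelConfig()
    policy = policy or AugmentationPolicy()
    rng = np.random.default_rng(seed)
    plans = make_splits(
        examples, settings.mutually_exclusive, n_reps=n_reps, rng=rng, train_size=train_size
    )
    ps, rs, fs = [], [], []
    for plan in plans:
        rep = plan.repetition_index
        p, r, f = _run_one_rep(
            examples, plan, task, settings, model_config, policy, focal_gamma,
            model_rng=np.random.default_rng([seed, rep, 1]),
            train_rng=np.random.default_rng([seed, rep, 2]),
            aug_rng=np.random.default_rng([seed, rep, 3]),
        )
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return EvalResult(
        arm=arm, task=task, precisions=np.array(ps), recalls=np.array(rs),
        f1s=np.array(fs), train_size=train_size,
    )


def training_size_sweep(
    task: str,
    examples: list[FeatureExample],
    sizes: tuple[int, ...] = tuple(range(540, 721, 30)),
    model_config: ModelConfig | None = None,
    policy: AugmentationPolicy | None = None,
    n_reps: int = N_REPETITIONS,
    seed: int = 0,
    focal_gamma: float = 2.0,
) -> list[EvalResult]:
    """Individual-exclusive, augmented, focal-loss runs at growing train sizes.

    Test individuals (and the 100 test segments) are fixed across sizes
    within a repetition, smaller training sets are prefixes of larger ones,
    and the model initialization is blocked on the repetition (shared across
    sizes), so within a repetition the training-set size is the only thing
    that varies.
    """
    model_config = model_config or ModelConfig()
    policy = policy or AugmentationPolicy()
    settings = ARM_SETTINGS["E2C"]
    rng = np.random.default_rng(seed)
    max_size = max(sizes)
    base_plans = make_splits(
        examples, mutually_exclusive=True, n_reps=n_reps, rng=rng, train_size=max_size
    )
    per_size: dict[int, list[tuple[float, float, float]]] = {s: [] for s in sizes}
    for plan in base_plans:
        rep = plan.repetition_index
        for size in sizes:
            sub = SplitPlan(
                repetition_index=rep,
                mutually_exclusive=True,
                test_individuals=plan.test_individuals,
                train_individuals=plan.train_individuals,
                train_indices=plan.train_indices[:size],
                test_indices=plan.test_indices,
                seed=plan.seed,
            )
            per_size[size].append(
                _run_one_rep(
                    examples, sub, task, settings, model_config, policy, focal_gamma,
                    model_rng=np.random.default_rng([seed, rep, 1]),
                    train_rng=np.random.default_rng([seed, rep, size, 2]),
                    aug_rng=np.random.default_rng([seed, rep, size, 3]),
                )
            )
    results = []
    for size in sizes:
        ps, rs, fs = map(np.array, zip(*per_size[size]))
        results.append(
            EvalResult(arm="E3", task=task, precisions=ps, recalls=rs, f1s=fs, train_size=size)
        )
    return results


def sweep_frame(results: list[EvalResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        m, s = res.mean_sd("f1")
        rows.append({"train_size": res.train_size, "f1_mean": m, "f1_sd": s})
    return pd.DataFrame(rows)


def plot_sweep(results: list[EvalResult], path: str | Path) -> None:
    """Mean +- SD F1 against training-set size (the learning-curve figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep_frame(results)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(df["train_size"], 100 * df["f1_mean"], yerr=100 * df["f1_sd"],
                marker="o", capsize=3)
    ax.set_xlabel("training clips")
    ax.set_ylabel("F1 (%)")
    ax.set_title(f"{results[0].task} task, {results[0].n_reps} repetitions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
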