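"""SE-attention convolutional classifier and its training loop.

The backbone is a small SE-ResNet-style stack sized for single-channel
173 x 64 MFCC inputs: a strided conv stem, a few conv+SE stages that
downsample, global average pooling, and a 2-way softmax head.  The SE blocks
(squeeze: per-channel global average; excite: bottleneck MLP with sigmoid;
rescale: channel-wise multiply) can be ablated with ``use_se=False``.

Two named presets bracket the configuration space: ``full_profile`` uses
the full optimization settings (batch 32, learning rate 1e-3, 100 epochs),
``test_profile`` is a lighter model trained for 20 epochs for desk-scale
runs.  Training is plain mini-batch Adam, fully seeded, so a run
is bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._layers import Adam, Conv2d, GlobalAvgPool, Layer, Linear, ReLU, SEBlock
from .loss import LossFn, make_cross_entropy, softmax


@dataclass(frozen=True)
class SEBlockConfig:
    channels: int
    reduction_ratio: int = 16


@dataclass(frozen=True)
class ModelConfig:
    input_shape: tuple[int, int, int] = (1, 173, 64)
    stem_channels: int = 16
    stem_kernel: int = 3
    stem_stride: int = 2
    stage_channels: tuple[int, ...] = (32, 64, 128)
    stage_kernel: int = 3
    stage_stride: int = 2
    use_se: bool = True
    reduction_ratio: int = 16
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0


def full_profile(**overrides) -> ModelConfig:
    """Full-scale preset: batch 32, learning rate 1e-3, 100 epochs."""
    return ModelConfig(**overrides)


def test_profile(**overrides) -> ModelConfig:
    """Lighter preset for desk-scale runs: smaller net, 20 epochs."""
    defaults = dict(
        stem_channels=8,
        stem_kernel=5,
        stem_stride=4,
        stage_channels=(16, 32),
        epochs=20,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


# --- the three SE primitives, exposed standalone for inspection/testing -----


def se_squeeze(fmap: np.ndarray) -> np.ndarray:
    """Global average pool each channel of a (C, H, W) map to a scalar."""
    if fmap.ndim != 3:
        raise ValueError("expected a (channels, height, width) feature map")
    return fmap.mean(axis=(1, 2))


def se_excite(
    z: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """sigmoid(W2 relu(W1 z + b1) + b2): per-channel weights, all in (0, 1)."""
    h = np.maximum(w1 @ z + b1, 0.0)
    return 1.0 / (1.0 + np.exp(-(w2 @ h + b2)))


def se_rescale(fmap: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Multiply channel c of the map by weights[c]."""
    if weights.shape[0] != fmap.shape[0]:
        raise ValueError(
            f"{weights.shape[0]} weights for {fmap.shape[0]} channels"
        )
    return fmap * weights[:, None, None]


@dataclass
class TrainingLog:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)


class SECallNet:
    """The classifier object: layer stack + input normalizer + train/predict."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.layers: list[Layer] = []
        c_in = config.input_shape[0]
        self.layers.append(Conv2d(c_in, config.stem_channels, config.stem_kernel,
                                  config.stem_stride, rng))
        self.layers.append(ReLU())
        c = config.stem_channels
        for c_out in config.stage_channels:
            self.layers.append(Conv2d(c, c_out, config.stage_kernel, config.stage_stride, rng))
            self.layers.append(ReLU())
            if config.use_se:
                self.layers.append(SEBlock(c_out, config.reduction_ratio, rng))
            c = c_out
        self.layers.append(GlobalAvgPool())
        self.layers.append(Linear(c, config.n_classes, rng))
        # input standardization (fit on the training set, per MFCC coefficient)
        n_coeffs = config.input_shape[2]
        self.norm_mean = np.zeros(n_coeffs, dtype=np.float32)
        self.norm_std = np.ones(n_coeffs, dtype=np.float32)

    # -- plumbing ------------------------------------------------------------

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x.astype(np.float32) - self.norm_mean) / self.norm_std

    def fit_normalizer(self, x: np.ndarray) -> None:
        self.norm_mean = x.mean(axis=(0, 1, 2)).astype(np.float32)
        self.norm_std = (x.std(axis=(0, 1, 2)) + 1e-6).astype(np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self._normalize(x)
        for layer in self.layers:
            y = layer.forward(y, train)
        return y

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    # -- inference -----------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities on the 2-simplex for a (N, 1, H, W) batch."""
        self._check_shape(x)
        out = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected (N, {', '.join(map(str, self.config.input_shape))}) input, "
                f"got {x.shape}"
            )

    # -- persistence ---------------------------------------------------------

    CHECKPOINT_SCHEMA = 1

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays["norm_mean"] = self.norm_mean
        arrays["norm_std"] = self.norm_std
        cfg = asdict(self.config)
        header = json.dumps({"schema": self.CHECKPOINT_SCHEMA, "config": cfg})
        np.savez(path, __meta__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SECallNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("schema") != cls.CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
            cfg_dict = meta["config"]
            for key in ("input_shape", "stage_channels"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict), np.random.default_rng(0))
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
            model.norm_mean = data["norm_mean"]
            model.norm_std = data["norm_std"]
        return model


def build_model(config: ModelConfig, rng: np.random.Generator | None = None) -> SECallNet:
    """Construct a seeded classifier; same seed, same initial parameters."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return SECallNet(config, rng)


def train(
    model: SECallNet,
    x: np.ndarray,
    y: np.ndarray,
    loss_fn: LossFn | None = None,
    config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TrainingLog:
    """Mini-batch Adam for ``config.epochs`` epochs; returns the loss curve.

    The input normalizer is fit on ``x`` before the first step.  A non-finite
    batch loss aborts with the epoch index in the error.
    """
    if len(x) == 0:
        raise ValueError("empty training set")
    config = config or model.config
    loss_fn = loss_fn or make_cross_entropy()
    rng = rng or np.random.default_rng(config.seed + 1)
    model._check_shape(x)
    model.fit_normalizer(x)
    y = np.asarray(y, dtype=np.int64)
    optimizer = Adam(model.params(), lr=config.learning_rate)
    log = TrainingLog()
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = loss_fn(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log.epoch_loss.append(float(np.mean(losses)))
        log.epoch_accuracy.append(n_correct / n)
    return log


def save_training_log(path: str | Path, log: TrainingLog) -> None:
    import pandas as pd

    pd.DataFrame(
        {"epoch": range(len(log.epoch_loss)), "loss": log.epoch_loss,
         "train_accuracy": log.epoch_accuracy}
    ).to_csv(path, index=False)
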