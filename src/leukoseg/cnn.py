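"""Four-block convolutional classifier for leukocyte crops, in pure numpy.

The network is built from a declarative :class:`CnnArchitectureSpec`.  The
default spec encodes the four-block topology used throughout this package:

* block 1 — 3 conv (3x3, 32 filters), 2 batch-norm, 2 ReLU, dropout, 2x2 max-pool
* block 2 — 3 conv (64 filters), 2 batch-norm, 2 ReLU, dropout
* block 3 — 2 conv (128 filters), 2 batch-norm, 2 ReLU
* block 4 — 3 conv (128 filters), 2 batch-norm, 2 ReLU, dropout

plus a head dropout after global average pooling, for a census of 11
convolution, 8 batch-norm, 8 ReLU and 4 dropout layers (the blocks alone
carry three).
Convolutions are valid (no padding) with stride 1; pooling has stride 2.
A global average pool feeds a linear hidden dense layer and a 4-way softmax
output (the census fixes all eight ReLUs inside the blocks, so the hidden
dense carries no activation).

Everything — im2col convolution, batch normalization, inverted dropout,
Adam, and the training loop — is implemented here on top of numpy, so seeded
runs are bit-reproducible on a given BLAS.  Layout is NHWC throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .imageio_core import LabeledDataset, as_rgb_image

__all__ = [
    "BlockSpec",
    "CnnArchitectureSpec",
    "TrainConfig",
    "TrainingHistory",
    "build_model",
    "count_parameters",
    "train",
    "predict",
    "dataset_to_arrays",
    "Sequential",
]

N_CLASSES = 4


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass
class BlockSpec:
    """One convolutional block: convs interleaved with BN/ReLU, then
    optional dropout and 2x2 max-pooling."""

    conv_layers: int
    filters: int
    batch_norm: int
    relu: int
    dropout: bool
    pool: bool = False

    def validate(self) -> None:
        if self.conv_layers < 1 or self.filters < 1:
            raise ValueError(f"block needs >= 1 conv layer and >= 1 filter: {self}")
        if not 0 <= self.batch_norm <= self.conv_layers:
            raise ValueError(f"batch_norm count must be in [0, conv_layers]: {self}")
        if not 0 <= self.relu <= self.conv_layers:
            raise ValueError(f"relu count must be in [0, conv_layers]: {self}")


@dataclass
class CnnArchitectureSpec:
    """Declarative description of the whole network."""

    input_size: int = 128
    blocks: list[BlockSpec] = field(default_factory=lambda: [
        BlockSpec(3, 32, 2, 2, dropout=True, pool=True),
        BlockSpec(3, 64, 2, 2, dropout=True),
        BlockSpec(2, 128, 2, 2, dropout=False),
        BlockSpec(3, 128, 2, 2, dropout=True),
    ])
    kernel_size: int = 3
    hidden_units: int = 64
    n_classes: int = N_CLASSES
    dropout_rate: float = 0.25
    head_dropout: bool = True

    @classmethod
    def compact(cls) -> "CnnArchitectureSpec":
        """Desk-scale variant: same four-block topology and layer census,
        reduced filter widths and a 48-pixel input."""
        return cls(
            input_size=48,
            blocks=[
                BlockSpec(3, 8, 2, 2, dropout=True, pool=True),
                BlockSpec(3, 16, 2, 2, dropout=True),
                BlockSpec(2, 32, 2, 2, dropout=False),
                BlockSpec(3, 32, 2, 2, dropout=True),
            ],
            hidden_units=32,
        )

    def validate(self) -> None:
        if self.input_size < 1 or self.n_classes < 2 or self.hidden_units < 1:
            raise ValueError("input_size, n_classes and hidden_units must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not self.blocks:
            raise ValueError("architecture needs at least one block")
        size = self.input_size
        for b in self.blocks:
            b.validate()
            size -= b.conv_layers * (self.kernel_size - 1)
            if b.pool:
                size //= 2
            if size < 1:
                raise ValueError(
                    f"spatial size collapses to {size} before the head; "
                    f"input_size {self.input_size} is too small for these blocks"
                )

    def layer_census(self) -> dict[str, int]:
        """Counts of conv / batch-norm / ReLU / dropout / pool layers."""
        return {
            "conv": sum(b.conv_layers for b in self.blocks),
            "batch_norm": sum(b.batch_norm for b in self.blocks),
            "relu": sum(b.relu for b in self.blocks),
            "dropout": sum(1 for b in self.blocks if b.dropout) + int(self.head_dropout),
            "pool": sum(1 for b in self.blocks if b.pool),
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CnnArchitectureSpec":
        d = json.loads(s)
        d["blocks"] = [BlockSpec(**b) for b in d["blocks"]]
        return cls(**d)


@dataclass
class TrainConfig:
    """Optimization settings: Adam, batch size 32, 12 epochs by default."""

    optimizer: str = "adam"
    batch_size: int = 32
    epochs: int = 12
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"only the Adam optimizer is supported, got {self.optimizer!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: trainable ``params`` with matching ``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def non_trainable_count(self) -> int:
        return 0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, OH, OW, C*k*k) patch matrix (C-major windows)."""
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    n, oh, ow = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n, oh, ow, -1)


class Conv2D(Layer):
    """Valid 2-D convolution (cross-correlation), stride 1, bias included."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = k * k * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.params = [w.astype(np.float64), np.zeros(c_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training, rng):
        self._x_shape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols if training else None
        w, b = self.params
        return cols @ w + b

    def backward(self, dout):
        w, _ = self.params
        n, oh, ow, f = dout.shape
        cols2 = self._cols.reshape(-1, self.k * self.k * self.c_in)
        dflat = dout.reshape(-1, f)
        self.grads[0][...] = cols2.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        # dx: full correlation of dout with the spatially flipped kernel,
        # in/out channels swapped.
        w4 = w.reshape(self.c_in, self.k, self.k, self.c_out)
        wflip = w4[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (F, k, k, C_in)
        p = self.k - 1
        dpad = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0)))
        cols_d = _im2col(dpad, self.k)
        dx = cols_d @ wflip.reshape(-1, self.c_in)
        assert dx.shape == self._x_shape
        self._cols = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W); running stats for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = [np.ones(channels), np.zeros(channels)]  # gamma, beta
        self.grads = [np.zeros(channels), np.zeros(channels)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def non_trainable_count(self) -> int:
        return self.running_mean.size + self.running_var.size

    def forward(self, x, training, rng):
        gamma, beta = self.params
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd, axes)
        return gamma * xhat + beta

    def backward(self, dout):
        gamma, _ = self.params
        xhat, invstd, axes = self._cache
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.grads[0][...] = (dout * xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * gamma
        dx = (invstd / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        mask = x > 0
        self._mask = mask if training else None
        return x * mask

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at eval."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max-pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x6 = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
        out = x6.max(axis=(2, 4))
        if training:
            self._cache = (x6, out, x.shape)
        return out

    def backward(self, dout):
        x6, out, x_shape = self._cache
        mask = x6 == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx6 = mask * (dout[:, :, None, :, None, :] / counts)
        n, h, w, c = x_shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(x_shape)
        dx[:, : h2 * 2, : w2 * 2] = dx6.reshape(n, h2 * 2, w2 * 2, c)
        self._cache = None
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = [w, np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training, rng):
        self._x = x if training else None
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        self._x = None
        return dout @ w.T


class Sequential:
    """Ordered layer container with forward/backward passes."""

    def __init__(self, layers: Sequence[Layer], spec: Optional[CnnArchitectureSpec] = None):
        self.layers = list(layers)
        self.spec = spec

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def census(self) -> dict[str, int]:
        kinds = {Conv2D: "conv", BatchNorm: "batch_norm", ReLU: "relu",
                 Dropout: "dropout", MaxPool2x2: "pool", GlobalAvgPool: "gap",
                 Dense: "dense"}
        counts = {v: 0 for v in kinds.values()}
        for layer in self.layers:
            counts[kinds[type(layer)]] += 1
        return counts

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"l{i}_p{j}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"l{i}_rmean"] = layer.running_mean
                arrays[f"l{i}_rvar"] = layer.running_var
        spec_json = self.spec.to_json() if self.spec else ""
        np.savez(path, __spec__=np.array(spec_json), **arrays)

    @classmethod
    def load(cls, path) -> "Sequential":
        data = np.load(path, allow_pickle=False)
        spec = CnnArchitectureSpec.from_json(str(data["__spec__"]))
        model = build_model(spec, seed=0)
        for i, layer in enumerate(model.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"l{i}_p{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = data[f"l{i}_rmean"]
                layer.running_var[...] = data[f"l{i}_rvar"]
        return model


# ---------------------------------------------------------------------------
# Model construction and parameter accounting
# ---------------------------------------------------------------------------

def build_model(spec: CnnArchitectureSpec | None = None, seed: int = 0) -> Sequential:
    """Instantiate the network described by ``spec`` with He-normal init."""
    spec = spec or CnnArchitectureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    c_in = 3
    for block in spec.blocks:
        for i in range(block.conv_layers):
            layers.append(Conv2D(c_in, block.filters, spec.kernel_size, rng))
            c_in = block.filters
            if i < block.batch_norm:
                layers.append(BatchNorm(block.filters))
            if i < block.relu:
                layers.append(ReLU())
        if block.dropout:
            layers.append(Dropout(spec.dropout_rate))
        if block.pool:
            layers.append(MaxPool2x2())
    layers.append(GlobalAvgPool())
    if spec.head_dropout:
        layers.append(Dropout(spec.dropout_rate))
    layers.append(Dense(c_in, spec.hidden_units, rng))
    layers.append(Dense(spec.hidden_units, spec.n_classes, rng))
    return Sequential(layers, spec)


def count_parameters(model: Sequential) -> tuple[int, int, int]:
    """Return ``(total, trainable, non_trainable)`` parameter counts.

    Per layer: a k x k convolution holds ``(k*k*c_in + 1) * c_out``, a dense
    layer ``(n_in + 1) * n_out``; batch-norm holds ``2C`` trainable
    (gamma, beta) plus ``2C`` non-trainable running statistics.
    """
    trainable = sum(p.size for p in model.parameters())
    non_trainable = sum(layer.non_trainable_count() for layer in model.layers)
    return trainable + non_trainable, trainable, non_trainable


# ---------------------------------------------------------------------------
# Loss, optimizer, training loop
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def dataset_to_arrays(dataset: LabeledDataset, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Resize crops to the network input size and scale intensities to [0, 1]."""
    xs = np.empty((len(dataset), input_size, input_size, 3), dtype=np.float64)
    ys = np.empty(len(dataset), dtype=np.int64)
    for i, rec in enumerate(dataset.records):
        img = as_rgb_image(rec.image)
        if img.shape[0] == input_size and img.shape[1] == input_size:
            xs[i] = img / 255.0
        else:
            xs[i] = resize(img, (input_size, input_size), preserve_range=True,
                           anti_aliasing=True) / 255.0
        ys[i] = rec.label.value
    return xs, ys


def calibrate_batchnorm(model: Sequential, x: np.ndarray, batch_size: int = 64) -> None:
    """Recompute batch-norm running statistics from the data in ``x``.

    Short training runs leave the exponential moving averages lagging far
    behind the batch statistics the network was actually trained with, which
    wrecks inference-mode accuracy.  This pass streams ``x`` through the
    network using batch statistics (dropout disabled) and replaces each
    running mean/variance with the average batch moments.
    """
    bns = [layer for layer in model.layers if isinstance(layer, BatchNorm)]
    if not bns:
        return
    acc: dict[int, list] = {id(bn): [] for bn in bns}
    for i in range(0, len(x), batch_size):
        xb = x[i:i + batch_size]
        for layer in model.layers:
            if isinstance(layer, BatchNorm):
                axes = tuple(range(xb.ndim - 1))
                mean = xb.mean(axis=axes)
                var = xb.var(axis=axes)
                acc[id(layer)].append((mean, var))
                gamma, beta = layer.params
                xb = gamma * (xb - mean) / np.sqrt(var + layer.eps) + beta
            elif isinstance(layer, Dropout):
                continue
            else:
                xb = layer.forward(xb, False, None)
    for bn in bns:
        means, variances = zip(*acc[id(bn)])
        bn.running_mean = np.mean(means, axis=0)
        bn.running_var = np.mean(variances, axis=0)


def _evaluate(model: Sequential, x: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], training=False)
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: Sequential,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig | None = None,
) -> tuple[Sequential, TrainingHistory]:
    """Minimize softmax cross-entropy with Adam; record per-epoch metrics.

    Shuffling and dropout are driven by a generator seeded from
    ``cfg.seed``, so identical inputs and seed give identical runs.
    """
    cfg = cfg or TrainConfig()
    x_train, y_train = train_data
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / len(x_train))
        history.train_acc.append(epoch_correct / len(x_train))
        if val_data is not None:
            calibrate_batchnorm(model, x_train, cfg.batch_size)
            vl, va = _evaluate(model, *val_data)
            history.val_loss.append(vl)
            history.val_acc.append(va)
    calibrate_batchnorm(model, x_train, cfg.batch_size)
    return model, history


def predict(model: Sequential, images: np.ndarray,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties go to the lower index)."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    probs = []
    for i in range(0, len(images), batch_size):
        probs.append(softmax(model.forward(images[i:i + batch_size], training=False)))
    p = np.concatenate(probs, axis=0)
    return p, p.argmax(axis=1)
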