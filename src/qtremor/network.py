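"""Model construction and training.

Two architectures are built here:

* the classical baseline: conv(16 @ 3x3, same) -> dropout -> maxpool 2x2 ->
  conv(16 @ 3x3, same) -> dropout -> flatten -> dense(32) -> dropout(0.5)
  -> dense(4) softmax, on a 32 x 215 input (first conv output 32x215x16,
  pooled to 16x107x16);

* the hybrid network: two conv + batch-norm + pool + dropout blocks followed
  by fully connected layers fc1..fc4 whose final two units feed the
  QuantClass decision head through a per-qubit angle encoding
  theta_i = (pi/2) * tanh(w_i . x + b_i).  The same trunk is also available
  with a dense-4 softmax head in place of the quantum one.

Training uses cross-entropy loss, the Adam optimizer, a polynomially
decaying learning rate and optional label-noise augmentation of the
training split.  Everything is plain numpy with explicit per-layer
backward passes; the QuantClass head backpropagates via the
parameter-shift rule.  Training always runs the configured epoch count
(no early stopping) and is bitwise reproducible from its seed in exact
evaluation mode.
"""

from __future__ import annotations

import dataclasses
import math
import time
from dataclasses import dataclass

import numpy as np

from .quantclass import QuantClassConfig, QuantClassHead

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainResult",
    "ArrayDataset",
    "cross_entropy",
    "polynomial_lr",
    "add_label_noise",
    "build_model",
    "train",
    "evaluate",
    "one_hot",
]

N_CLASSES = 4


# ---------------------------------------------------------------------------
# losses and schedules
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def cross_entropy(targets: np.ndarray, predictions: np.ndarray) -> float:
    """L = -(1/N) sum_i sum_c y_ic log p_ic, predictions clipped to [1e-12, 1]."""
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if targets.shape != predictions.shape:
        raise ValueError(f"shape mismatch: {targets.shape} vs {predictions.shape}")
    if np.any(np.abs(predictions.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("prediction rows must sum to 1")
    p = np.clip(predictions, 1e-12, 1.0)
    return float(-(targets * np.log(p)).sum() / targets.shape[0])


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr0: float = 1e-3
    end_lr: float = 1e-5
    power: float = 1.0
    horizon: int | None = None  # defaults to the total step count
    label_noise: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")


def polynomial_lr(step: int, cfg: TrainConfig) -> float:
    """lr = end_lr + (lr0 - end_lr) (1 - step/horizon)^power, clamped past
    the horizon."""
    horizon = cfg.horizon or 1
    if step >= horizon:
        return cfg.end_lr
    frac = 1.0 - step / horizon
    return cfg.end_lr + (cfg.lr0 - cfg.end_lr) * frac**cfg.power


def add_label_noise(labels: np.ndarray, rate: float, seed: int = 0,
                    n_classes: int = N_CLASSES) -> np.ndarray:
    """Replace each label, independently with probability ``rate``, by a
    uniformly drawn *different* class (the augmentation used on the
    training split)."""
    labels = np.asarray(labels, dtype=int)
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("labels must lie in 0..n_classes-1")
    rng = np.random.default_rng(seed)
    flip = rng.random(labels.shape) < rate
    offsets = rng.integers(1, n_classes, size=labels.shape)
    noisy = labels.copy()
    noisy[flip] = (labels[flip] + offsets[flip]) % n_classes
    return noisy


# ---------------------------------------------------------------------------
# layers (B, H, W, C) / (B, F) with explicit backward passes
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3 'same' convolution, channels-last, im2col based."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = 9 * c_in
        self.params["w"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), (fan_in, c_out))
        self.params["b"] = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=False, rng=None):
        b, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (B, H, W, C, 3, 3) -> (B, H, W, 3, 3, C)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(b, h, w, -1)
        self._shape = (b, h, w)
        return self._cols @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        b, h, w = self._shape
        flat_cols = self._cols.reshape(-1, 9 * self.c_in)
        flat_dout = dout.reshape(-1, self.c_out)
        self.grads["w"] = flat_cols.T @ flat_dout
        self.grads["b"] = flat_dout.sum(axis=0)
        dcols = (flat_dout @ self.params["w"].T).reshape(b, h, w, 3, 3, self.c_in)
        dxp = np.zeros((b, h + 2, w + 2, self.c_in))
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1:-1, 1:-1, :]


class ReLU(_Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(_Layer):
    """2x2 max pooling, stride 2; odd remainder rows/columns are dropped."""

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :h2 * 2, :w2 * 2, :]
        r = xc.reshape(b, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(b, h2, w2, c, 4)
        self._arg = r.argmax(axis=4)
        return r.max(axis=4)

    def backward(self, dout):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((b, h2, w2, c, 4))
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=4)
        dx = np.zeros((b, h, w, c))
        dx[:, :h2 * 2, :w2 * 2, :] = (
            dr.reshape(b, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(b, h2 * 2, w2 * 2, c)
        )
        return dx


class BatchNorm(_Layer):
    """Per-channel batch normalisation over (B, H, W); running stats in eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = np.prod([x.shape[a] for a in axes])
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) / std


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class InputCenter(_Layer):
    """Fixed affine input normalisation x -> 2x - 1 ([0, 1] to [-1, 1])."""

    def forward(self, x, train=False, rng=None):
        return 2.0 * x - 1.0

    def backward(self, dout):
        return 2.0 * dout


class Flatten(_Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_std: float | None = None):
        super().__init__()
        std = math.sqrt(2.0 / n_in) if init_std is None else init_std
        self.params["w"] = rng.normal(0.0, std, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------

class SoftmaxHead:
    """Dense logits -> softmax probabilities; CE gradient (p - y)/B."""

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, logits, train=False, rng=None):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def loss_grad(self, targets):
        # d(CE)/d(logits) for softmax, averaged over the batch
        return (self._p - targets) / targets.shape[0]


class QuantClassNetHead:
    """Angle encoding plus the two-qubit head.

    Input (B, 2) from fc4 -> per-angle pre-activations z_a = w_a . x + b_a ->
    theta_a = pi tanh(z_a) -> outcome probabilities (B, 4).  n_angles = 2
    gives one angle per qubit (the trainable default); n_angles = 1 is the
    shared-angle form, which leaves p01 = p10 degenerate.
    """

    def __init__(self, rng: np.random.Generator, n_angles: int = 2,
                 cfg: QuantClassConfig | None = None):
        if n_angles not in (1, 2):
            raise ValueError("n_angles must be 1 or 2")
        self.n_angles = n_angles
        self.cfg = cfg or QuantClassConfig()
        self.head = QuantClassHead(self.cfg)
        # n_angles=2: identity map (unit i drives qubit i) so the two angles
        # start distinguishable; n_angles=1: w1 = w2 = 1, b = 0.
        w0 = np.eye(2)[:, :n_angles] if n_angles == 2 else np.ones((2, 1))
        self.params = {"w": w0.copy(), "b": np.zeros(n_angles)}
        self.grads = {}

    # (pi/2) * tanh keeps theta in the monotone branch of sin: the per-qubit
    # marginal (1 + sin theta)/2 is then a strictly increasing link in z
    scale = math.pi / 2.0

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._z = x @ self.params["w"] + self.params["b"]
        self._t = np.tanh(self._z)
        thetas = self.scale * self._t
        self._p = self.head.forward(thetas)
        return self._p

    def loss_grad(self, targets):
        b = targets.shape[0]
        dp = -(targets / np.clip(self._p, 1e-12, 1.0)) / b
        dtheta = self.head.backward(dp)  # (B, n_angles)
        dz = dtheta * self.scale * (1.0 - self._t**2)
        self.grads["w"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["w"].T  # gradient w.r.t. fc4 output


# ---------------------------------------------------------------------------
# model spec / assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative description of either network.

    kind 'classical' reproduces the printed baseline on a 32x215 input;
    kind 'hybrid' is the two-block conv + fc1..fc4 trunk with either the
    QuantClass head ('quantclass') or a dense-4 softmax ('softmax').
    """

    kind: str = "hybrid"
    input_shape: tuple[int, int, int] = (32, 215, 1)
    conv_filters: int = 16
    dropout_conv: float = 0.2
    dropout_dense: float = 0.5
    dense_width: int = 32                      # classical only
    fc_widths: tuple[int, ...] = (256, 64, 16, 2)  # hybrid only
    head: str = "quantclass"
    head_mode: str = "functional"
    n_angles: int = 2
    center_input: bool = True
    jitter_sigma: float = 0.0
    head_eval: str = "exact"
    shots: int = 1024

    def __post_init__(self) -> None:
        if self.kind not in ("classical", "hybrid"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.head not in ("quantclass", "softmax"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.kind == "classical":
            self.head = "softmax"  # the printed baseline ends in dense-4 softmax
        if self.fc_widths[-1] != 2:
            raise ValueError("fc4 must have 2 units (they feed the angle encoding)")


class Network:
    """A trunk of layers plus a head, with explicit forward/backward."""

    def __init__(self, layers, head, seed: int = 0):
        self.layers = layers
        self.head = head
        self.seed = seed

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return self.head.forward(x, train=train, rng=rng)

    def backward(self, targets):
        dout = self.head.loss_grad(targets)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x, batch_size: int = 64):
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i:i + batch_size], train=False))
        return np.concatenate(outs, axis=0)

    def parameters(self):
        for obj in list(self.layers) + [self.head]:
            for name in sorted(obj.params):
                yield obj, name


def _trunk_shapes(spec: ModelSpec):
    h, w, c = spec.input_shape
    return h, w, c


def build_model(spec: ModelSpec, seed: int = 0) -> Network:
    """Assemble a trainable network from its spec; weights are seeded."""
    rng = np.random.default_rng(seed)
    h, w, c = _trunk_shapes(spec)
    if h < 4 or w < 4:
        raise ValueError(f"input {spec.input_shape} too small for the conv trunk")
    nf = spec.conv_filters
    layers: list[_Layer] = []
    if spec.center_input:
        layers.append(InputCenter())
    if spec.kind == "classical":
        layers += [Conv2D(c, nf, rng), ReLU(), Dropout(spec.dropout_conv), MaxPool2()]
        layers += [Conv2D(nf, nf, rng), ReLU(), Dropout(spec.dropout_conv), Flatten()]
        flat = (h // 2) * (w // 2) * nf
        layers += [Dense(flat, spec.dense_width, rng), ReLU(), Dropout(spec.dropout_dense),
                   Dense(spec.dense_width, N_CLASSES, rng)]
        head = SoftmaxHead()
    else:
        layers += [Conv2D(c, nf, rng), BatchNorm(nf), ReLU(), MaxPool2(),
                   Dropout(spec.dropout_conv)]
        layers += [Conv2D(nf, nf, rng), BatchNorm(nf), ReLU(), MaxPool2(),
                   Dropout(spec.dropout_conv), Flatten()]
        flat = (h // 2 // 2) * (w // 2 // 2) * nf
        widths = list(spec.fc_widths)
        prev = flat
        for wd in widths[:-1]:
            layers += [Dense(prev, wd, rng), ReLU()]
            prev = wd
        # small init keeps the angle encoder out of tanh saturation at start
        layers += [Dense(prev, widths[-1], rng, init_std=0.1)]
        if spec.head == "quantclass":
            cfg = QuantClassConfig(mode=spec.head_mode, jitter_sigma=spec.jitter_sigma,
                                   eval=spec.head_eval, shots=spec.shots, seed=seed)
            head = QuantClassNetHead(rng, n_angles=spec.n_angles, cfg=cfg)
        else:
            layers += [Dense(widths[-1], N_CLASSES, rng)]
            head = SoftmaxHead()
    return Network(layers, head, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """In-memory split arrays; X in (N, H, W, C) channels-last layout."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray


@dataclass
class TrainResult:
    epoch_train_loss: list[float]
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float
    test_loss: float
    test_accuracy: float
    seconds: float
    seed: int
    config: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class _Adam:
    def __init__(self, net: Network, cfg: TrainConfig):
        self.cfg = cfg
        self.state = {}
        for i, (obj, name) in enumerate(net.parameters()):
            self.state[(id(obj), name)] = [np.zeros_like(obj.params[name]),
                                           np.zeros_like(obj.params[name])]
        self.t = 0

    def step(self, net: Network, lr: float):
        cfg = self.cfg
        self.t += 1
        for obj, name in net.parameters():
            g = obj.grads.get(name)
            if g is None:
                continue
            m, v = self.state[(id(obj), name)]
            m[:] = cfg.beta1 * m + (1 - cfg.beta1) * g
            v[:] = cfg.beta2 * v + (1 - cfg.beta2) * g * g
            mhat = m / (1 - cfg.beta1**self.t)
            vhat = v / (1 - cfg.beta2**self.t)
            obj.params[name] -= lr * mhat / (np.sqrt(vhat) + cfg.eps)


def evaluate(model: Network, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(cross-entropy loss, accuracy); argmax class rule, ties to the lowest
    class index."""
    if x.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty split")
    p = model.predict_proba(x)
    loss = cross_entropy(one_hot(y), p)
    acc = float((p.argmax(axis=1) == np.asarray(y)).mean())
    return loss, acc


def train(model: Network, dataset: ArrayDataset, cfg: TrainConfig) -> TrainResult:
    """Train for exactly ``cfg.epochs`` epochs; label noise is applied to the
    training split only, once, before training."""
    for name in ("x_train", "x_val", "x_test"):
        if getattr(dataset, name).shape[0] == 0:
            raise ValueError(f"empty split: {name}")
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    y_noisy = add_label_noise(dataset.y_train, cfg.label_noise, seed=cfg.seed + 1)
    x, y = dataset.x_train, one_hot(y_noisy)
    n = x.shape[0]
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    if cfg.horizon is None:
        cfg = dataclasses.replace(cfg, horizon=cfg.epochs * steps_per_epoch)
    opt = _Adam(model, cfg)
    epoch_losses = []
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            probs = model.forward(x[idx], train=True, rng=rng)
            losses.append(cross_entropy(y[idx], probs))
            model.backward(y[idx])
            opt.step(model, polynomial_lr(step, cfg))
            step += 1
        epoch_losses.append(float(np.mean(losses)))
    tr_loss, tr_acc = evaluate(model, dataset.x_train, dataset.y_train)
    va_loss, va_acc = evaluate(model, dataset.x_val, dataset.y_val)
    te_loss, te_acc = evaluate(model, dataset.x_test, dataset.y_test)
    return TrainResult(
        epoch_train_loss=epoch_losses,
        train_loss=tr_loss, train_accuracy=tr_acc,
        val_loss=va_loss, val_accuracy=va_acc,
        test_loss=te_loss, test_accuracy=te_acc,
        seconds=time.perf_counter() - t0,
        seed=cfg.seed,
        config=dataclasses.asdict(cfg),
    )
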