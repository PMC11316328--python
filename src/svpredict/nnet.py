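"""A small feed-forward / 1-D convolutional network engine in numpy.

Implements exactly the pieces the prediction study needs: dense and 1-D
convolutional layers with ReLU/tanh/linear/sigmoid activations, L1+L2
weight penalties, max-pooling, inverted dropout, a concatenation trunk for
multi-input networks, and SGD / Adam / RMSprop optimizers with the usual
library default learning rates. Gradients are hand-derived and checked
against finite differences in the test suite.

Conventions: dense inputs are ``(batch, features)``; convolutional inputs
are ``(batch, length, channels)``. Dropout is active only while training,
so evaluation of a trained model is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "linear":
        return np.ones_like(z)
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a**2
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def penalty(self) -> float:
        return 0.0


class Dense(Layer):
    """Affine map + activation with optional L1/L2 weight penalties."""

    def __init__(self, units: int, activation: str = "linear",
                 l1: float = 0.0, l2: float = 0.0):
        self.units = units
        self.activation = activation
        self.l1, self.l2 = l1, l2
        self.W = None
        self.b = np.zeros(units)

    def build(self, n_in: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (n_in + self.units))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, self.units))
        self.b = np.zeros(self.units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False, rng=None):
        if self.W is None:
            raise RuntimeError("layer not built")
        self._x = x
        self._z = x @ self.W + self.b
        self._a = _act(self.activation, self._z)
        return self._a

    def backward(self, grad):
        dz = grad * _act_grad(self.activation, self._z, self._a)
        self.dW = self._x.T @ dz
        if self.l1:
            self.dW += self.l1 * np.sign(self.W)
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def penalty(self):
        pen = 0.0
        if self.l1:
            pen += self.l1 * np.abs(self.W).sum()
        if self.l2:
            pen += self.l2 * np.square(self.W).sum()
        return pen


class Conv1D(Layer):
    """1-D convolution (valid padding, shared weights across windows)."""

    def __init__(self, filters: int, kernel_width: int = 3, stride: int = 1,
                 activation: str = "linear", l1: float = 0.0, l2: float = 0.0):
        self.filters = filters
        self.kernel_width = kernel_width
        self.stride = stride
        self.activation = activation
        self.l1, self.l2 = l1, l2
        self.W = None  # (kernel_width, channels, filters)
        self.b = np.zeros(filters)

    def build(self, length: int, channels: int, rng: np.random.Generator) -> None:
        if length < self.kernel_width:
            raise ValueError(f"input length {length} shorter than kernel "
                             f"width {self.kernel_width}")
        fan_in = self.kernel_width * channels
        limit = np.sqrt(6.0 / (fan_in + self.filters))
        self.W = rng.uniform(-limit, limit, size=(self.kernel_width, channels, self.filters))
        self.b = np.zeros(self.filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_length(self, length: int) -> int:
        return (length - self.kernel_width) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        # x: (batch, length, channels)
        win = sliding_window_view(x, self.kernel_width, axis=1)[:, ::self.stride]
        # win: (batch, T, channels, kernel_width)
        self._win_shape = x.shape
        self._win = win
        self._z = np.einsum("btck,kcf->btf", win, self.W) + self.b
        self._a = _act(self.activation, self._z)
        return self._a

    def backward(self, grad):
        dz = grad * _act_grad(self.activation, self._z, self._a)
        self.dW = np.einsum("btf,btck->kcf", dz, self._win)
        if self.l1:
            self.dW += self.l1 * np.sign(self.W)
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db = dz.sum(axis=(0, 1))
        dx = np.zeros(self._win_shape)
        T = dz.shape[1]
        for k in range(self.kernel_width):
            # contribution of kernel tap k to positions k, k+s, ...
            dx[:, k:k + self.stride * T:self.stride, :] += dz @ self.W[k].T
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def penalty(self):
        pen = 0.0
        if self.l1:
            pen += self.l1 * np.abs(self.W).sum()
        if self.l2:
            pen += self.l2 * np.square(self.W).sum()
        return pen


class MaxPool1D(Layer):
    """Max pooling along the length axis; default stride = pool width."""

    def __init__(self, width: int = 2, stride: int | None = None):
        self.width = width
        self.stride = width if stride is None else stride

    def out_length(self, length: int) -> int:
        return (length - self.width) // self.stride + 1

    def forward(self, x, training=False, rng=None):
        win = sliding_window_view(x, self.width, axis=1)[:, ::self.stride]
        # win: (batch, T, channels, width)
        self._x_shape = x.shape
        self._arg = win.argmax(axis=-1)
        self._out = win.max(axis=-1)
        return self._out

    def backward(self, grad):
        dx = np.zeros(self._x_shape)
        T = grad.shape[1]
        for w in range(self.width):
            mask = self._arg == w
            dx[:, w:w + self.stride * T:self.stride, :] += grad * mask
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise RuntimeError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class Network:
    """A sequential stack of layers over a single input block."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def build(self, input_shape: tuple[int, ...], seed: int = 0) -> "Network":
        """Initialize parameters for inputs of the given per-sample shape."""
        rng = np.random.default_rng(seed)
        shape = tuple(input_shape)
        for layer in self.layers:
            if isinstance(layer, Dense):
                if len(shape) != 1:
                    raise ValueError("Dense after unflattened conv output")
                layer.build(shape[0], rng)
                shape = (layer.units,)
            elif isinstance(layer, Conv1D):
                length, channels = shape if len(shape) == 2 else (shape[0], 1)
                layer.build(length, channels, rng)
                shape = (layer.out_length(length), layer.filters)
            elif isinstance(layer, MaxPool1D):
                shape = (layer.out_length(shape[0]), shape[1])
            elif isinstance(layer, Flatten):
                shape = (int(np.prod(shape)),)
        self.output_shape = shape
        return self

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x) -> np.ndarray:
        """Deterministic evaluation-mode forward pass."""
        return self.forward(x, training=False)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)


class MultiInputNetwork:
    """Parallel branches merged by concatenation into a shared trunk."""

    def __init__(self, branches: list[list[Layer]], trunk: list[Layer]):
        self.branches = [Network(b) for b in branches]
        self.trunk = Network(trunk)

    def build(self, input_shapes: list[tuple[int, ...]], seed: int = 0) -> "MultiInputNetwork":
        if len(input_shapes) != len(self.branches):
            raise ValueError("one input shape per branch required")
        widths = []
        for i, (br, shape) in enumerate(zip(self.branches, input_shapes)):
            br.build(shape, seed=seed + i)
            widths.append(br.output_shape[0])
        self._split = np.cumsum(widths)[:-1]
        self.trunk.build((int(sum(widths)),), seed=seed + len(self.branches))
        return self

    def forward(self, xs, training=False, rng=None):
        outs = [br.forward(x, training=training, rng=rng)
                for br, x in zip(self.branches, xs)]
        merged = np.concatenate(outs, axis=1)
        return self.trunk.forward(merged, training=training, rng=rng)

    def backward(self, grad):
        gmerged = self.trunk.backward(grad)
        parts = np.split(gmerged, self._split, axis=1)
        return [br.backward(g) for br, g in zip(self.branches, parts)]

    def predict(self, xs) -> np.ndarray:
        return self.forward(xs, training=False)

    def params(self):
        out = [p for br in self.branches for p in br.params()]
        return out + self.trunk.params()

    def grads(self):
        out = [g for br in self.branches for g in br.grads()]
        return out + self.trunk.grads()

    def penalty(self) -> float:
        return sum(br.penalty() for br in self.branches) + self.trunk.penalty()


# ---------------------------------------------------------------------------
# optimizers (library-default learning rates)
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, lr: float = 0.01):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class RMSprop:
    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._v = None

    def step(self, params, grads):
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.rho
            v += (1.0 - self.rho) * g**2
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = self._v = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        c1 = 1.0 - self.beta1**self._t
        c2 = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str):
    try:
        return OPTIMIZERS[name]()
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _loss_and_grad(kind: str, y: np.ndarray, pred: np.ndarray):
    """Data loss and its gradient w.r.t. the network output."""
    y = y.reshape(-1, 1)
    n = y.shape[0]
    if kind == "quantitative":  # MSE
        diff = pred - y
        return float(np.mean(diff**2)), 2.0 * diff / n
    if kind == "binary":  # binary cross-entropy on sigmoid output
        p = np.clip(pred, _EPS, 1.0 - _EPS)
        loss = -float(np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
        return loss, (p - y) / (p * (1.0 - p)) / n
    raise ValueError(f"unknown trait kind {kind!r}")


@dataclass
class TrainedModel:
    model: Network | MultiInputNetwork
    history: dict[str, list[float]] = field(default_factory=dict)
    best_val_loss: float = np.inf
    best_epoch: int = -1
    seed: int = 0

    def predict(self, x) -> np.ndarray:
        return self.model.predict(x)


def _iter_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _take(x, idx):
    if isinstance(x, (list, tuple)):
        return [xi[idx] for xi in x]
    return x[idx]


def fit_network(model, X, y, X_val=None, y_val=None, *, kind: str = "quantitative",
                optimizer: str = "adam", epochs: int = 100, batch_size: int = 32,
                patience: int = 10, seed: int = 0) -> TrainedModel:
    """Mini-batch training with early stopping on validation loss.

    Minimizes MSE (quantitative) or binary cross-entropy (binary) plus any
    layer weight penalties. Stops when the validation loss has not improved
    for ``patience`` epochs and restores the best epoch's parameters.
    Returns the model with its per-epoch train/validation history.
    """
    rng = np.random.default_rng(seed)
    opt = make_optimizer(optimizer)
    n = y.shape[0]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_params = None
    has_val = X_val is not None and y_val is not None

    for epoch in range(epochs):
        for idx in _iter_batches(n, batch_size, rng):
            pred = model.forward(_take(X, idx), training=True, rng=rng)
            _, grad = _loss_and_grad(kind, np.asarray(y)[idx], pred)
            model.backward(grad)
            if np.any([not np.all(np.isfinite(g)) for g in model.grads()]):
                raise FloatingPointError(
                    f"non-finite gradient at epoch {epoch}; reduce the learning "
                    f"rate or the penalty weights (optimizer={optimizer})")
            opt.step(model.params(), model.grads())

        train_pred = model.predict(X)
        train_loss, _ = _loss_and_grad(kind, np.asarray(y), train_pred)
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        history["train_loss"].append(train_loss)
        if has_val:
            val_pred = model.predict(X_val)
            val_loss, _ = _loss_and_grad(kind, np.asarray(y_val), val_pred)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_epoch = epoch
                best_params = [p.copy() for p in model.params()]
            elif epoch - best_epoch >= patience:
                break
        else:
            if train_loss < best_val:
                best_val = train_loss
                best_epoch = epoch

    if best_params is not None:
        for p, bp in zip(model.params(), best_params):
            p[...] = bp
    return TrainedModel(model=model, history=history, best_val_loss=best_val,
                        best_epoch=best_epoch, seed=seed)
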