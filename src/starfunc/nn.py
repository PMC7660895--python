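"""Minimal convolutional network engine on numpy.

Implements exactly the pieces the haplotype-function models need: 1-D
convolution over channels-last binary sequence matrices, ReLU, non-
overlapping max pooling, dense layers, inverted dropout, three loss heads
(softmax cross-entropy, mean squared error, sum of per-output binary
cross-entropies on sigmoid outputs), an Adam optimizer with seeded
minibatch training, and reference-based attribution.

Attribution follows the DeepLIFT rescale rule: multipliers are propagated
backwards from a chosen output, with linear layers contributing their
weights, elementwise nonlinearities the ratio of output to input
differences-from-reference, and max pooling distributing its output
difference across window inputs in proportion to their squared input
differences. Every per-layer rule satisfies sum_i m_i * dx_i = dy exactly,
so the summation-to-delta property holds to numerical precision for the
whole network.

Inputs are arrays of shape (N, L, C); all arithmetic is float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

_EPS = 1e-10


# ---------------------------------------------------------------------------
# layers

class Layer:
    """Base layer: forward/backward plus DeepLIFT multiplier propagation."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dl_backward(self, m_out: np.ndarray, x_in: np.ndarray,
                    x_ref: np.ndarray, y_out: np.ndarray,
                    y_ref: np.ndarray) -> np.ndarray:
        """Propagate DeepLIFT multipliers from output to input."""
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution spanning the full channel depth."""

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        fan_in = width * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(fan_in, out_channels)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, L, C) -> (N, Lout, width*C), window-position-major ordering
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # win: (N, Lout, C, width) -> (N, Lout, width, C)
        win = win.transpose(0, 1, 3, 2)
        n, lout = win.shape[:2]
        return np.ascontiguousarray(win).reshape(
            n, lout, self.width * self.in_channels)

    def forward(self, x, train=False, rng=None):
        cols = self._im2col(x)
        if train:
            self._cols, self._in_len = cols, x.shape[1]
        return cols @ self.W + self.b

    def backward(self, dy):
        cols = self._cols
        self.dW[...] = np.tensordot(cols, dy, axes=([0, 1], [0, 1]))
        self.db[...] = dy.sum(axis=(0, 1))
        return self._cols_to_input(dy @ self.W.T, self._in_len)

    def _cols_to_input(self, dcols: np.ndarray, in_len: int) -> np.ndarray:
        n, lout = dcols.shape[:2]
        dcols = dcols.reshape(n, lout, self.width, self.in_channels)
        dx = np.zeros((n, in_len, self.in_channels), dtype=np.float32)
        for i in range(self.width):
            dx[:, i:i + lout, :] += dcols[:, :, i, :]
        return dx

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        # linear: multipliers propagate through the weights
        return self._cols_to_input(m_out @ self.W.T, x_in.shape[1])

    def out_shape(self, in_shape):
        length, channels = in_shape
        if channels != self.in_channels:
            raise ValueError(
                f"conv expects {self.in_channels} channels, got {channels}")
        out_len = length - self.width + 1
        if out_len <= 0:
            raise ValueError(
                f"conv width {self.width} exceeds input length {length}")
        return (out_len, self.out_channels)


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        dx = x_in - x_ref
        dy = y_out - y_ref
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(np.abs(dx) > _EPS, dy / np.where(dx == 0, 1, dx),
                             (x_in > 0).astype(np.float32))
        return m_out * ratio

    def out_shape(self, in_shape):
        return in_shape


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a truncated tail is dropped."""

    def __init__(self, width: int):
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width
        self._idx: np.ndarray | None = None
        self._in_len = 0

    def _windows(self, x: np.ndarray) -> np.ndarray:
        n, length, channels = x.shape
        lout = length // self.width
        return x[:, :lout * self.width].reshape(n, lout, self.width, channels)

    def forward(self, x, train=False, rng=None):
        win = self._windows(x)
        if train:
            self._idx = win.argmax(axis=2)
            self._in_len = x.shape[1]
        return win.max(axis=2)

    def backward(self, dy):
        n, lout, channels = dy.shape
        dwin = np.zeros((n, lout, self.width, channels), dtype=np.float32)
        np.put_along_axis(dwin, self._idx[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        dx = np.zeros((n, self._in_len, channels), dtype=np.float32)
        dx[:, :lout * self.width] = dwin.reshape(n, lout * self.width,
                                                 channels)
        return dx

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        # distribute the output delta over window inputs in proportion to
        # their squared deltas; exact per-window summation-to-delta
        dwin = self._windows(x_in) - self._windows(x_ref)
        dy = y_out - y_ref
        denom = (dwin ** 2).sum(axis=2)
        scale = np.where(denom > _EPS, dy / np.where(denom == 0, 1, denom),
                         0.0)
        mwin = m_out[:, :, None, :] * dwin * scale[:, :, None, :]
        n, lout, _, channels = mwin.shape
        m_in = np.zeros_like(x_in, dtype=np.float32)
        m_in[:, :lout * self.width] = mwin.reshape(n, lout * self.width,
                                                   channels)
        return m_in

    def out_shape(self, in_shape):
        length, channels = in_shape
        out_len = length // self.width
        if out_len == 0:
            raise ValueError(
                f"pool width {self.width} reduces length {length} to 0")
        return (out_len, channels)


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        return m_out.reshape(x_in.shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        return m_out @ self.W.T

    def out_shape(self, in_shape):
        if in_shape != (self.in_features,):
            raise ValueError(
                f"dense expects {(self.in_features,)}, got {in_shape}")
        return (self.out_features,)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / \
            (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask

    def dl_backward(self, m_out, x_in, x_ref, y_out, y_ref):
        return m_out

    def out_shape(self, in_shape):
        return in_shape


# ---------------------------------------------------------------------------
# network

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A feed-forward stack of layers with an output head.

    ``head`` is one of ``"softmax"`` (classification over K classes),
    ``"sigmoid"`` (independent per-output probabilities) or ``"linear"``
    (regression). :meth:`forward` returns pre-activation logits;
    :meth:`predict` applies the head activation, batching the input.
    """

    def __init__(self, layers: Sequence[Layer], head: str,
                 input_shape: tuple[int, int]):
        if head not in {"softmax", "sigmoid", "linear"}:
            raise ValueError(f"unknown head {head!r}")
        self.layers = list(layers)
        self.head = head
        self.input_shape = tuple(input_shape)
        shape: tuple[int, ...] = self.input_shape
        for layer in self.layers:
            shape = layer.out_shape(shape)
        self.output_dim = shape[0]

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = x.astype(np.float32, copy=False)
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h

    def activate(self, logits: np.ndarray) -> np.ndarray:
        if self.head == "softmax":
            return _softmax(logits)
        if self.head == "sigmoid":
            return _sigmoid(logits)
        return logits

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.activate(self.forward(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    # -- parameters --------------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    # -- attribution -------------------------------------------------------
    def deeplift(self, x: np.ndarray, x_ref: np.ndarray, output_index: int,
                 post_activation: bool = True) -> tuple[np.ndarray, float]:
        """Reference-based attribution of one output to input positions.

        Returns ``(attributions, delta)`` where ``attributions`` has the
        input shape and ``delta`` is the output difference the attributions
        sum to. ``post_activation`` attributes the activated output (for
        sigmoid heads); for softmax heads the class logit is attributed.
        """
        if x.shape != x_ref.shape:
            raise ValueError(f"shape mismatch {x.shape} vs {x_ref.shape}")
        single = x.ndim == 2
        if single:
            x, x_ref = x[None], x_ref[None]
        xa = x.astype(np.float32)
        xr = x_ref.astype(np.float32)

        cache: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        ha, hr = xa, xr
        for layer in self.layers:
            ya = layer.forward(ha)
            yr = layer.forward(hr)
            cache.append((ha, hr, ya, yr))
            ha, hr = ya, yr

        logit_a, logit_r = ha[:, output_index], hr[:, output_index]
        use_act = post_activation and self.head == "sigmoid"
        if use_act:
            out_a, out_r = _sigmoid(logit_a), _sigmoid(logit_r)
            dz = logit_a - logit_r
            seed_val = np.where(
                np.abs(dz) > _EPS, (out_a - out_r) / np.where(dz == 0, 1, dz),
                out_a * (1 - out_a))
        else:
            out_a, out_r = logit_a, logit_r
            seed_val = np.ones_like(logit_a)

        m = np.zeros_like(ha, dtype=np.float32)
        m[:, output_index] = seed_val
        for layer, (ca, cr, ya, yr) in zip(reversed(self.layers),
                                           reversed(cache)):
            m = layer.dl_backward(m, ca, cr, ya, yr)

        attrib = m * (xa - xr)
        delta = out_a - out_r
        if single:
            return attrib[0], float(delta[0])
        return attrib, delta


# ---------------------------------------------------------------------------
# losses (computed on logits)

def softmax_cross_entropy(logits: np.ndarray,
                          y: np.ndarray) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    p = _softmax(logits)
    loss = -float(np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def mean_squared_error(logits: np.ndarray,
                       y: np.ndarray) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    pred = logits[:, 0]
    resid = pred - y
    loss = float(np.mean(resid ** 2))
    dlogits = np.zeros_like(logits)
    dlogits[:, 0] = 2.0 * resid / n
    return loss, dlogits


def sum_binary_cross_entropy(logits: np.ndarray,
                             t: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum over outputs of binary cross-entropy on sigmoid logits."""
    n = logits.shape[0]
    p = _sigmoid(logits)
    loss = float(np.mean(
        np.sum(-(t * np.log(np.clip(p, 1e-12, None)) +
                 (1 - t) * np.log(np.clip(1 - p, 1e-12, None))), axis=1)))
    return loss, (p - t) / n


LOSSES: dict[str, Callable[[np.ndarray, np.ndarray],
                           tuple[float, np.ndarray]]] = {
    "softmax": softmax_cross_entropy,
    "linear": mean_squared_error,
    "sigmoid": sum_binary_cross_entropy,
}


# ---------------------------------------------------------------------------
# optimizer and training loop

class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _eval_loss(net: Network, x: np.ndarray, y: np.ndarray, loss_fn,
               batch_size: int) -> float:
    total, n = 0.0, len(x)
    for i in range(0, n, batch_size):
        xb = x[i:i + batch_size].astype(np.float32)
        loss, _ = loss_fn(net.forward(xb), y[i:i + batch_size])
        total += loss * len(xb)
    return total / n


def fit(net: Network, x: np.ndarray, y: np.ndarray, *,
        epochs: int, batch_size: int, lr: float,
        rng: np.random.Generator,
        x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
        patience: int | None = None,
        verbose: bool = False) -> FitHistory:
    """Train with Adam on shuffled minibatches.

    If validation data and ``patience`` are given, training stops once the
    validation loss has not improved for ``patience`` epochs and the best
    weights (lowest validation loss) are restored.
    """
    loss_fn = LOSSES[net.head]
    opt = Adam(net.params(), lr=lr)
    hist = FitHistory()
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    stall = 0
    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            xb = x[idx].astype(np.float32)
            yb = y[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = loss_fn(logits, yb)
            net.backward(dlogits)
            opt.step(net.grads())
            total += loss * len(idx)
        hist.train_loss.append(total / n)
        if x_val is not None:
            vloss = _eval_loss(net, x_val, y_val, loss_fn, batch_size)
            hist.val_loss.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_weights = net.get_weights()
                hist.best_epoch = epoch
                stall = 0
            else:
                stall += 1
            if verbose:
                print(f"epoch {epoch}: train {hist.train_loss[-1]:.4f} "
                      f"val {vloss:.4f}")
            if patience is not None and stall >= patience:
                break
        elif verbose:
            print(f"epoch {epoch}: train {hist.train_loss[-1]:.4f}")
    if best_weights is not None:
        net.set_weights(best_weights)
    return hist
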