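"""Minimal 1D convolutional network engine with hand-written backprop.

Implements exactly the layer vocabulary the spectral classifier needs —
1D convolution (stride 1, same padding), batch normalisation, ReLU,
max-pooling (window 2, stride 2), dropout, fully connected layers — together
with reverse-mode gradients and the rectified-Adam (RAdam) optimiser.
Computation is float32 throughout; convolutions are lowered to matrix
multiplication via an im2col transform so the heavy lifting happens in BLAS.

Writing the engine by hand keeps the gradient path fully inspectable, which
the Grad-CAM interpretation stage exploits: gradients of a class logit with
respect to intermediate feature maps are ordinary intermediate quantities
here, checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F = np.float32


class Layer:
    """Base layer: `forward` caches what `backward` needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Stride-1, same-padding 1D convolution (odd kernel size).

    Padding is reflective rather than zero: spectra are smooth curves, and
    zero padding would introduce artificial step edges whose feature
    activations contaminate gradient-based attribution at the axis ends.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        pad_mode: str = "reflect",
    ):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for exact same padding")
        if pad_mode not in ("reflect", "zero"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.pad_mode = pad_mode
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel
        # He-normal init, appropriate for ReLU nets
        self.params["W"] = (
            rng.standard_normal((c_out, c_in * kernel)) * np.sqrt(2.0 / fan_in)
        ).astype(F)
        self.params["b"] = np.zeros(c_out, dtype=F)

    def forward(self, x, train, rng):
        B, C, L = x.shape
        p = (self.k - 1) // 2
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (p, p)),
            mode="reflect" if self.pad_mode == "reflect" else "constant",
        )
        cols = sliding_window_view(xp, self.k, axis=2)  # (B, C, L, k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            B * L, C * self.k
        )
        self._cols, self._shape = cols, (B, C, L)
        y = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(y.reshape(B, L, self.c_out).transpose(0, 2, 1))

    def backward(self, dy):
        B, C, L = self._shape
        p = (self.k - 1) // 2
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        self.grads["W"] = dy2.T @ self._cols
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"]).reshape(B, L, C, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + 2 * p), dtype=F)
        for j in range(self.k):  # col2im scatter-add, k <= 21
            dxp[:, :, j : j + L] += dcols[:, :, :, j]
        self._cols = None
        dx = dxp[:, :, p : p + L].copy()
        if self.pad_mode == "reflect":
            # fold gradients of the reflected cells back onto their sources
            for i in range(p):
                dx[:, :, p - i] += dxp[:, :, i]
                dx[:, :, L - 2 - i] += dxp[:, :, p + L + i]
        return dx


class BatchNorm(Layer):
    """Batch normalisation over (batch, length) for conv maps or (batch,) for FC."""

    def __init__(self, n_channels: int, conv: bool, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.conv, self.momentum, self.eps = conv, momentum, eps
        self.params["gamma"] = np.ones(n_channels, dtype=F)
        self.params["beta"] = np.zeros(n_channels, dtype=F)
        self.running_mean = np.zeros(n_channels, dtype=F)
        self.running_var = np.ones(n_channels, dtype=F)

    def _bshape(self, x):
        return (1, -1, 1) if self.conv else (1, -1)

    def forward(self, x, train, rng):
        axes = (0, 2) if self.conv else (0,)
        sh = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(F)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(F)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._cache = (xhat, inv, train, axes, sh)
        return self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)

    def backward(self, dy):
        xhat, inv, train, axes, sh = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"].reshape(sh)
        if not train:  # affine transform with frozen statistics
            return dy * g * inv.reshape(sh)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh)
        ) * inv.reshape(sh)
        self._cache = None
        return dx.astype(F)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """Max pooling, window 2, stride 2; odd trailing element is dropped."""

    def forward(self, x, train, rng):
        B, C, L = x.shape
        if L < 2:
            raise ValueError("feature map too short to pool")
        Lo = L // 2
        a = x[:, :, 0 : 2 * Lo : 2]
        b = x[:, :, 1 : 2 * Lo : 2]
        self._left = a >= b
        self._in_len = L
        return np.where(self._left, a, b)

    def backward(self, dy):
        B, C, Lo = dy.shape
        dx = np.zeros((B, C, self._in_len), dtype=F)
        dx[:, :, 0 : 2 * Lo : 2] = np.where(self._left, dy, 0)
        dx[:, :, 1 : 2 * Lo : 2] = np.where(self._left, 0, dy)
        return dx


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(F) / F(1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = (
            rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)
        ).astype(F)
        self.params["b"] = np.zeros(n_out, dtype=F)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"]
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{i}.{name}", layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for key, layer, name in self.parameters():
            state[key] = layer.params[name].copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            layer.params[name] = state[key].copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


class RAdam:
    """Rectified Adam: Adam with a warm-up-free variance rectification term.

    Falls back to an un-adapted (momentum-only) update while the variance
    estimate is untrustworthy (rho_t <= 4), then switches to the rectified
    adaptive step.
    """

    def __init__(self, model: Sequential, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t, b1, b2 = self.t, self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(F)
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**t)
            if rho_t > 4.0:
                r = np.sqrt(
                    (rho_t - 4.0)
                    * (rho_t - 2.0)
                    * self.rho_inf
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                v_hat = np.sqrt(v / (1 - b2**t))
                layer.params[name] -= (self.lr * r * m_hat / (v_hat + self.eps)).astype(F)
            else:
                layer.params[name] -= (self.lr * m_hat).astype(F)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy.

    Per-sample losses are weighted by the true class's weight and normalised
    by the sum of the applied weights, so re-scaling the weight vector does
    not change the loss.
    """
    n = len(y)
    p = softmax(logits.astype(np.float64))
    w = class_weights[y]
    wsum = w.sum()
    loss = float((w * -np.log(p[np.arange(n), y] + 1e-12)).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(F)


def weighted_logsigmoid_nll(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-class log-sigmoid scores with a weighted negative log-likelihood.

    Treats the four outputs as independent log-sigmoid scores (one-vs-rest
    Bernoulli likelihood); each sample's loss is weighted by its true class's
    weight. Provided for parity with the log-sigmoid output head; softmax
    cross-entropy is the default training loss.
    """
    n, c = logits.shape
    z = logits.astype(np.float64)
    t = np.zeros((n, c))
    t[np.arange(n), y] = 1.0
    # stable log(sigmoid(z)) and log(1 - sigmoid(z))
    log_sig = -np.logaddexp(0.0, -z)
    log_one_minus = -np.logaddexp(0.0, z)
    w = class_weights[y]
    wsum = w.sum()
    per_sample = -(t * log_sig + (1 - t) * log_one_minus).sum(axis=1)
    loss = float((w * per_sample).sum() / wsum)
    dlogits = (1.0 / (1.0 + np.exp(-z)) - t) * (w / wsum)[:, None]
    return loss, dlogits.astype(F)
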