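"""Minimal NHWC convolutional-network engine in numpy.

Self-contained layers (standard / depthwise / pointwise convolution,
batch normalization, ReLU, global average pooling, dense) with manual
backpropagation and an SGD-momentum optimizer with cosine learning-rate
decay.  Deliberately small: the networks in this package have a few
thousand parameters on ~17x17 inputs, so exact loop-over-kernel-offset
convolutions vectorized over the batch are more than fast enough.

Conventions: activations are float64 NHWC; weights are He-initialized
from a caller-supplied Generator so everything is reproducible from one
seed.
"""

from __future__ import annotations

import numpy as np


def _out_size(n: int, kernel: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - kernel) // stride + 1


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2D(Layer):
    """Standard convolution, NHWC, same-style zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2
        scale = np.sqrt(2.0 / (kernel * kernel * in_ch))
        self.params["w"] = rng.normal(0.0, scale, size=(kernel, kernel, in_ch, out_ch))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, h, w, _ = x.shape
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._xshape = xp, x.shape
        out = np.zeros((n, ho, wo, self.params["w"].shape[3]))
        for a in range(k):
            for b in range(k):
                patch = xp[:, a : a + s * ho : s, b : b + s * wo : s, :]
                out += np.einsum("nijc,cd->nijd", patch, self.params["w"][a, b])
        return out + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = self._xp
        n, h, w, _ = self._xshape
        ho, wo = dy.shape[1], dy.shape[2]
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(self.params["w"])
        for a in range(k):
            for b in range(k):
                patch = xp[:, a : a + s * ho : s, b : b + s * wo : s, :]
                dw[a, b] = np.einsum("nijc,nijd->cd", patch, dy)
                dxp[:, a : a + s * ho : s, b : b + s * wo : s, :] += np.einsum(
                    "nijd,cd->nijc", dy, self.params["w"][a, b]
                )
        self.grads["w"] = dw
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dxp[:, p : p + h, p : p + w, :]


class DepthwiseConv2D(Layer):
    """Depthwise convolution: one spatial kernel per input channel."""

    def __init__(
        self, channels: int, kernel: int, stride: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.params["w"] = rng.normal(0.0, scale, size=(kernel, kernel, channels))
        self.params["b"] = np.zeros(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, h, w, c = x.shape
        ho, wo = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._xshape = xp, x.shape
        out = np.zeros((n, ho, wo, c))
        for a in range(k):
            for b in range(k):
                out += xp[:, a : a + s * ho : s, b : b + s * wo : s, :] * self.params[
                    "w"
                ][a, b]
        return out + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = self._xp
        n, h, w, c = self._xshape
        ho, wo = dy.shape[1], dy.shape[2]
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(self.params["w"])
        for a in range(k):
            for b in range(k):
                patch = xp[:, a : a + s * ho : s, b : b + s * wo : s, :]
                dw[a, b] = (patch * dy).sum(axis=(0, 1, 2))
                dxp[:, a : a + s * ho : s, b : b + s * wo : s, :] += (
                    dy * self.params["w"][a, b]
                )
        self.grads["w"] = dw
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._std = np.sqrt(var + self.eps)
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes, m = self._axes, self._m
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Sequential:
    """A stack of layers with softmax cross-entropy on top."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # ---- flat (de)serialization -----------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                state[f"L{i}.{name}"] = val
            if isinstance(layer, BatchNorm):
                state[f"L{i}.running_mean"] = layer.running_mean
                state[f"L{i}.running_var"] = layer.running_var
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"L{i}.{name}"])
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"L{i}.running_mean"])
                layer.running_var = np.asarray(state[f"L{i}.running_var"])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class SGDMomentum:
    """SGD with classical momentum and cosine learning-rate decay."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 0.01,
        momentum: float = 0.9,
        total_steps: int | None = None,
        weight_decay: float = 0.0,
    ) -> None:
        self.model = model
        self.lr0 = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.step_count = 0
        self.velocity: dict[tuple[int, str], np.ndarray] = {}

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.step_count / self.total_steps, 1.0)
        return self.lr0 * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self) -> None:
        lr = self.current_lr()
        for i, layer in enumerate(self.model.layers):
            for name, grad in layer.grads.items():
                if self.weight_decay and name in ("w",):  # decay weights, not biases/BN
                    grad = grad + self.weight_decay * layer.params[name]
                key = (i, name)
                v = self.velocity.get(key)
                v = grad if v is None else self.momentum * v + grad
                self.velocity[key] = v
                layer.params[name] = layer.params[name] - lr * v
        self.step_count += 1
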