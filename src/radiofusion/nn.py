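"""Minimal NumPy neural-network engine for small 3D convolutional models.

Provides exactly the layers the shallow 3D classifier needs — 3D convolution
(stride 1, padding 1, via im2col), batch normalization, leaky ReLU, 2x max
pooling, inverted dropout, global average pooling and fully connected layers —
with hand-written backward passes (validated by finite-difference gradient
checks in the test suite), SGD with momentum, and a cosine-annealing learning
rate schedule with warm restarts.  Being pure NumPy, training is bitwise
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def leaky_gain(slope: float) -> float:
    return float(np.sqrt(2.0 / (1.0 + slope**2)))


class Layer:
    """Base layer: optional params/grads dicts and forward/backward passes."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel k, stride 1, padding (k-1)/2 (shape-preserving)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        rng: np.random.Generator,
        gain: float,
        needs_input_grad: bool = True,
    ):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.needs_input_grad = needs_input_grad
        fan_in = in_ch * k**3
        std = gain / np.sqrt(fan_in)
        self.params["w"] = rng.normal(0.0, std, (out_ch, fan_in)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def _offsets(self):
        k = self.k
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def forward(self, x, training):
        B, C, D, H, W = x.shape
        k, p = self.k, (self.k - 1) // 2
        N = D * H * W
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        # im2col buffer (B, C, k^3, N); reshape to (B, C*k^3, N) is a view
        col = np.empty((B, C, k**3, N), dtype=x.dtype)
        for oi, (i, j, l) in enumerate(self._offsets()):
            col[:, :, oi, :] = xp[:, :, i : i + D, j : j + H, l : l + W].reshape(B, C, N)
        col = col.reshape(B, C * k**3, N)
        self._col = col
        self._spatial = (D, H, W)
        out = np.matmul(self.params["w"], col) + self.params["b"][None, :, None]
        return out.reshape(B, self.out_ch, D, H, W)

    def backward(self, grad):
        B = grad.shape[0]
        D, H, W = self._spatial
        k, p = self.k, (self.k - 1) // 2
        g = np.ascontiguousarray(grad.reshape(B, self.out_ch, -1))
        self.grads["b"] = g.sum(axis=(0, 2)).astype(np.float32)
        self.grads["w"] = (
            np.matmul(g, self._col.transpose(0, 2, 1)).sum(axis=0).astype(np.float32)
        )
        self._col = None
        if not self.needs_input_grad:  # first layer: nothing consumes dx
            return None
        dcol = np.matmul(self.params["w"].T, g)  # (B, C*k^3, N)
        dcol = dcol.reshape(B, self.in_ch, k**3, D, H, W)
        dxp = np.zeros(
            (B, self.in_ch, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32
        )
        for oi, (i, j, l) in enumerate(self._offsets()):
            dxp[:, :, i : i + D, j : j + H, l : l + W] += dcol[:, :, oi]
        return dxp[:, :, p : p + D, p : p + H, p : p + W]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def _shape(self, x):
        s = [1] * x.ndim
        s[1] = x.shape[1]
        return tuple(s)

    def forward(self, x, training):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        s = self._shape(x)
        if training:
            n = x.size // x.shape[1]
            s1 = x.sum(axis=axes, dtype=np.float64)
            sub = "bc,bc->c" if x.ndim == 2 else "bcdhw,bcdhw->c"
            s2 = np.einsum(sub, x, x)
            mean = (s1 / n).astype(x.dtype)
            var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0).astype(x.dtype)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(s)) * inv.reshape(s)
        if training:
            self._cache = (xhat, inv, axes, s)
        return self.params["gamma"].reshape(s) * xhat + self.params["beta"].reshape(s)

    def backward(self, grad):
        xhat, inv, axes, s = self._cache
        n = grad.size // grad.shape[1]
        self.grads["gamma"] = (grad * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = grad.sum(axis=axes).astype(np.float32)
        g = grad * self.params["gamma"].reshape(s)
        dx = (
            g
            - g.mean(axis=axes, keepdims=True)
            - xhat * (g * xhat).mean(axis=axes, keepdims=True)
        ) * inv.reshape(s)
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, training):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class MaxPool3d(Layer):
    """2x2x2 max pooling; trailing odd voxels are cropped."""

    def forward(self, x, training):
        B, C, D, H, W = x.shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        self._in_shape = x.shape
        xc = x[:, :, : 2 * D2, : 2 * H2, : 2 * W2]
        r = xc.reshape(B, C, D2, 2, H2, 2, W2, 2)
        if not training:
            return r.max(axis=(3, 5, 7))
        # gather the 8 cell corners along one axis so a single argmax suffices
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            B, C, D2, H2, W2, 8
        )
        self._arg = r.argmax(axis=-1)
        out = np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]
        return out

    def backward(self, grad):
        B, C, D, H, W = self._in_shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        dr = np.zeros((B, C, D2, H2, W2, 8), dtype=np.float32)
        np.put_along_axis(dr, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : 2 * D2, : 2 * H2, : 2 * W2] = (
            dr.reshape(B, C, D2, H2, W2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(B, C, 2 * D2, 2 * H2, 2 * W2)
        )
        self._arg = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training without an rng")
        self._mask = (
            self.rng.random(x.shape, dtype=np.float32) >= self.p
        ).astype(np.float32) / np.float32(1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(B, C, D, H, W) -> (B, C), averaging over space."""

    def forward(self, x, training):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        B, C, D, H, W = self._in_shape
        return np.broadcast_to(
            grad[:, :, None, None, None] / (D * H * W), self._in_shape
        ).astype(grad.dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float):
        super().__init__()
        std = gain / np.sqrt(n_in)
        self.params["w"] = rng.normal(0.0, std, (n_out, n_in)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = (grad.T @ self._x).astype(np.float32)
        self.grads["b"] = grad.sum(axis=0).astype(np.float32)
        dx = grad @ self.params["w"]
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield (li, name), layer, p

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{li}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm):
                state[f"{li}.running_mean"] = layer.running_mean.copy()
                state[f"{li}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{li}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{li}.running_mean"].copy()
                layer.running_var = state[f"{li}.running_var"].copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels; returns (loss, dlogits)."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean())
    dp = p.copy()
    dp[np.arange(B), y] -= 1.0
    return loss, (dp / B).astype(np.float32)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred.astype(np.float64) - target
    loss = float((diff**2).mean())
    return loss, (2.0 * diff / diff.size).astype(np.float32)


class SGD:
    """SGD with classical momentum."""

    def __init__(self, model: Sequential, momentum: float = 0.9):
        self.model = model
        self.momentum = momentum
        self.velocity = {
            key: np.zeros_like(p) for key, _, p in model.parameters()
        }

    def step(self, lr: float) -> None:
        for key, layer, p in self.model.parameters():
            g = layer.grads[key[1]]
            v = self.velocity[key]
            v *= self.momentum
            v -= lr * g
            p += v


def cosine_lr(epoch: int, base_lr: float, period: int, eta_min: float = 0.0) -> float:
    """Cosine annealing with warm restarts every ``period`` epochs.

    lr(e) = eta_min + (base - eta_min)/2 * (1 + cos(pi * (e mod period)/period));
    at every multiple of ``period`` the rate restarts at ``base_lr``.
    """
    t = epoch % period
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + np.cos(np.pi * t / period))
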