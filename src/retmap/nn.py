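"""Minimal NumPy neural-network engine for small CNN regressors.

Provides exactly what the per-location regressors need: strided 3x3
convolutions, ReLU, global average pooling, dense layers, Xavier-normal
initialization, mean-squared-error loss and the Nadam optimizer.
Everything is float64 and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Nadam",
    "xavier_normal",
]


def xavier_normal(rng: np.random.Generator, shape: tuple[int, ...],
                  fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier normal draw: N(0, sqrt(2 / (fan_in + fan_out)))."""
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class Layer:
    """Base layer: parameters live in ``params``, gradients in ``grads``."""

    #: set False on the first layer to skip the (unused) input gradient
    needs_input_grad: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (by default) convolution with 'same' padding and configurable stride.

    Input/output layout is (N, C, H, W).  Implemented as k*k shifted
    tensordot accumulations, which is fast for the small channel counts
    used here and keeps the backward pass simple.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: tuple[int, int] | int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        if isinstance(stride, int):
            stride = (stride, stride)
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = kernel
        self.stride = stride
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.params["W"] = xavier_normal(rng, (out_ch, in_ch, kernel, kernel),
                                         fan_in, fan_out)
        self.params["b"] = np.zeros(out_ch)
        self._cache: tuple | None = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        p = self.k // 2
        sr, sc = self.stride
        return ((h + 2 * p - self.k) // sr + 1, (w + 2 * p - self.k) // sc + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, p = self.k, self.k // 2
        sr, sc = self.stride
        ho, wo = self.out_shape(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # im2col: (N, C, ho, wo, k, k) -> (N*ho*wo, C*k*k)
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = view[:, :, 0:sr * ho:sr, 0:sc * wo:sc, :, :]
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * ho * wo, c * k * k)
        W = self.params["W"]
        wmat = W.transpose(1, 2, 3, 0).reshape(c * k * k, self.out_ch)
        out = cols @ wmat + self.params["b"]
        self._cache = (cols, (n, c, h, w), (ho, wo))
        out = out.reshape(n, ho, wo, self.out_ch)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, p = self.k, self.k // 2
        sr, sc = self.stride
        W = self.params["W"]
        dout_t = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        dwmat = cols.T @ dout_t  # (C*k*k, O)
        self.grads["W"] = np.ascontiguousarray(
            dwmat.reshape(c, k, k, self.out_ch).transpose(3, 0, 1, 2))
        self.grads["b"] = dout_t.sum(axis=0)
        if not self.needs_input_grad:
            return None
        wmat = W.transpose(1, 2, 3, 0).reshape(c * k * k, self.out_ch)
        dcols = (dout_t @ wmat.T).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + sr * ho:sr, dj:dj + sc * wo:sc] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.params["W"] = xavier_normal(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """A plain layer stack with weight (de)serialization helpers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": layer.params[name].copy()
                for i, layer in enumerate(self.layers) for name in layer.params}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, value in weights.items():
            idx, name = key.split(".", 1)
            target = self.layers[int(idx)].params[name]
            if target.shape != value.shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{target.shape} vs {value.shape}")
            target[...] = value


def cast_model(model: "Sequential", dtype) -> None:
    """In-place dtype cast of all parameters (e.g. float32 for training)."""
    for layer, name in model.parameters():
        layer.params[name] = layer.params[name].astype(dtype)


class Nadam:
    """Nesterov-momentum Adam (Dozat 2016), bias-corrected form.

    p -= lr * (beta1 * m_hat_next + (1 - beta1) * g_hat) / (sqrt(v_hat) + eps)
    """

    def __init__(self, model: Sequential, lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {id(layer.params[name]): np.zeros_like(layer.params[name])
                   for layer, name in model.parameters()}
        self._v = {id(layer.params[name]): np.zeros_like(layer.params[name])
                   for layer, name in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for layer, name in self.model.parameters():
            p = layer.params[name]
            g = layer.grads[name]
            m = self._m[id(p)]
            v = self._v[id(p)]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** (t + 1))
            g_hat = g / (1 - b1 ** t)
            v_hat = v / (1 - b2 ** t)
            p -= self.lr * (b1 * m_hat + (1 - b1) * g_hat) / (np.sqrt(v_hat) + self.eps)
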