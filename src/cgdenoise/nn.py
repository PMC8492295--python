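"""Minimal reverse-mode neural-network layers in numpy.

The networks in this package are small enough that a hand-written layer
library is both tractable and fully deterministic.  Conventions:

* Feature tensors are ``(N, C, H, W)`` float64 arrays; fully connected
  inputs are ``(N, D)``.
* Each layer caches, during ``forward``, exactly what its ``backward``
  needs; ``backward(dy)`` returns the gradient with respect to the
  layer's input and *accumulates* parameter gradients into
  ``layer.grads`` (call ``zero_grad`` between optimization steps).
* Convolution is computed as a sum over the k x k kernel offsets of
  channel-contraction matmuls (tensordot) against shifted views of the
  padded input.  This avoids materializing an im2col matrix, keeping
  peak memory at one feature map per layer and making full-resolution
  inference tractable.

All backward passes are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), optional stride, zero padding.

    Default padding ``kernel_size // 2`` preserves spatial size at
    stride 1.  Weights are initialized from N(0, weight_std^2), biases at
    zero.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        weight_std: float = 0.02,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        rng = np.random.default_rng() if rng is None else rng
        self._register(
            "weight",
            rng.normal(0.0, weight_std, (out_channels, in_channels, kernel_size, kernel_size)),
        )
        self._register("bias", np.zeros(out_channels))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        weight = self.params["weight"]
        acc = np.zeros((self.out_channels, n, ho, wo))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                acc += np.tensordot(weight[:, :, ki, kj], xs, axes=([1], [1]))
        self._cache = (x, ho, wo)
        return acc.transpose(1, 0, 2, 3) + self.params["bias"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, ho, wo = self._cache
        n, c, h, w = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        weight = self.params["weight"]
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                sl = (slice(None), slice(None), slice(ki, ki + s * ho, s), slice(kj, kj + s * wo, s))
                self.grads["weight"][:, :, ki, kj] += np.tensordot(
                    dy, xp[sl], axes=([0, 2, 3], [0, 2, 3])
                )
                dxs = np.tensordot(weight[:, :, ki, kj], dy, axes=([0], [1]))
                dxp[sl] += dxs.transpose(1, 0, 2, 3)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over spatial dimensions with affine."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self._register("gamma", np.ones(channels))
        self._register("beta", np.zeros(channels))

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.2) -> None:
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.negative_slope * dy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(negative_slope=0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        weight_std: float = 0.02,
    ) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = np.random.default_rng() if rng is None else rng
        self._register("weight", rng.normal(0.0, weight_std, (out_features, in_features)))
        self._register("bias", np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(f"expected {self.in_features} features, got {x.shape[1]}")
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["weight"] += dy.T @ self._x
        self.grads["bias"] += dy.sum(axis=0)
        return dy @ self.params["weight"]


class Module:
    """A named collection of layers with flat state-dict serialization."""

    def named_layers(self) -> list[tuple[str, Layer]]:  # pragma: no cover - interface
        raise NotImplementedError

    def param_items(self):
        for lname, layer in self.named_layers():
            for pname in layer.params:
                yield f"{lname}.{pname}", layer, pname

    def zero_grad(self) -> None:
        for _, layer in self.named_layers():
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(layer.params[p].size for _, layer, p in self.param_items())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: layer.params[p].copy() for key, layer, p in self.param_items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {key: (layer, p) for key, layer, p in self.param_items()}
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict keys do not match module: {sorted(missing)}")
        for key, (layer, p) in own.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != layer.params[p].shape:
                raise ValueError(f"shape mismatch for {key}")
            layer.params[p] = arr.copy()
            layer.grads[p] = np.zeros_like(arr)


class Adam:
    """Adam optimizer over a Module's parameters.

    Default betas (0.5, 0.9) follow common practice for Wasserstein
    critics, where high first-moment momentum destabilizes the
    alternating game.
    """

    def __init__(
        self,
        module: Module,
        lr: float,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
    ) -> None:
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.module = module
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[p]) for key, layer, p in module.param_items()}
        self.v = {key: np.zeros_like(layer.params[p]) for key, layer, p in module.param_items()}

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, layer, p in self.module.param_items():
            g = layer.grads[p]
            self.m[key] = b1 * self.m[key] + (1.0 - b1) * g
            self.v[key] = b2 * self.v[key] + (1.0 - b2) * g * g
            layer.params[p] -= self.lr * (self.m[key] / bc1) / (
                np.sqrt(self.v[key] / bc2) + self.eps
            )

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.m:
            self.m[k] = np.asarray(state["m"][k], dtype=np.float64).copy()
            self.v[k] = np.asarray(state["v"][k], dtype=np.float64).copy()
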