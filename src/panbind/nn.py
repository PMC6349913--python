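"""Minimal 1-D neural-network layers with explicit forward/backward passes.

Everything operates on float32 arrays of shape ``(batch, width, channels)``
(the unit height axis of the input tensors is dropped internally). Each
layer owns its parameters and accumulates parameter gradients during
``backward``; :class:`SGD` applies momentum updates. This is deliberately
the smallest layer set the binding-prediction architecture needs: valid/same
1-D convolution, batch normalization, leaky rectifier, max and adaptive
average pooling, a locally-connected layer (position-specific kernels, no
weight sharing across width), flatten and dense layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import NetworkShapeError

__all__ = [
    "Layer", "Conv1d", "LocallyConnected1d", "BatchNorm", "LeakyReLU",
    "MaxPool1d", "AdaptiveAvgPool1d", "Flatten", "Dense", "Sequential", "SGD",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_width(self, w: int) -> int:
        return w


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    """(B, W, C) -> (B, W-k+1, k*C) sliding windows, kernel-position major."""
    # sliding_window_view yields (B, W-k+1, C, k); reorder to (.., k, C).
    p = sliding_window_view(x, k, axis=1)
    p = np.ascontiguousarray(np.swapaxes(p, 2, 3))
    b, w_out = p.shape[:2]
    return p.reshape(b, w_out, k * x.shape[2])


def _scatter_patches(gp: np.ndarray, k: int, c_in: int, w_in: int) -> np.ndarray:
    """Adjoint of :func:`_patches`: (B, W_out, k*C) -> (B, W_in, C)."""
    b, w_out = gp.shape[:2]
    gp = gp.reshape(b, w_out, k, c_in)
    gx = np.zeros((b, w_in, c_in), dtype=gp.dtype)
    for i in range(k):
        gx[:, i:i + w_out, :] += gp[:, :, i, :]
    return gx


class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, 'same' or 'valid' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.c_in, self.c_out, self.k, self.padding = c_in, c_out, kernel, padding
        self.params["w"] = _he_init(rng, (kernel * c_in, c_out), kernel * c_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _pad(self) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        total = self.k - 1
        return total // 2, total - total // 2

    def out_width(self, w: int) -> int:
        if self.padding == "same":
            return w
        if self.k > w:
            raise NetworkShapeError(f"kernel {self.k} wider than input width {w}")
        return w - self.k + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[2] != self.c_in:
            raise NetworkShapeError(f"expected {self.c_in} channels, got {x.shape[2]}")
        p0, p1 = self._pad()
        xp = np.pad(x, ((0, 0), (p0, p1), (0, 0))) if (p0 or p1) else x
        if self.k > xp.shape[1]:
            raise NetworkShapeError(f"kernel {self.k} wider than input width {x.shape[1]}")
        self._xp_shape = xp.shape
        self._pat = _patches(xp, self.k)
        return self._pat @ self.params["w"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, w_out, _ = gout.shape
        g2 = gout.reshape(-1, self.c_out)
        self.grads["w"] = self._pat.reshape(-1, self.k * self.c_in).T @ g2
        self.grads["b"] = g2.sum(axis=0)
        gp = gout @ self.params["w"].T
        gxp = _scatter_patches(gp, self.k, self.c_in, self._xp_shape[1])
        p0, p1 = self._pad()
        if p0 or p1:
            gxp = gxp[:, p0:self._xp_shape[1] - p1, :]
        return gxp


class LocallyConnected1d(Layer):
    """Convolution-like layer whose kernel differs at every output position.

    With valid padding and kernel width k, an input of width W yields
    W' = W - k + 1 outputs; position i applies its own ``(k*c_in, c_out)``
    weight block to ``x[i : i+k]`` only. No weights are shared across width,
    so the layer can respond to a feature differently depending on where it
    occurs.
    """

    def __init__(self, w_in: int, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel > w_in:
            raise NetworkShapeError(f"kernel {kernel} wider than input width {w_in}")
        self.w_in, self.c_in, self.c_out, self.k = w_in, c_in, c_out, kernel
        self.w_out = w_in - kernel + 1
        self.params["w"] = _he_init(rng, (self.w_out, kernel * c_in, c_out), kernel * c_in)
        self.params["b"] = np.zeros((self.w_out, c_out), dtype=np.float32)

    def out_width(self, w: int) -> int:
        if w != self.w_in:
            raise NetworkShapeError(f"locally connected layer built for width {self.w_in}, got {w}")
        return self.w_out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.w_in or x.shape[2] != self.c_in:
            raise NetworkShapeError(
                f"expected (B, {self.w_in}, {self.c_in}), got {x.shape}")
        # position-major layout so each position is one BLAS matmul
        self._pat = np.ascontiguousarray(
            _patches(x, self.k).transpose(1, 0, 2))  # (W', B, k*C)
        y = self._pat @ self.params["w"]             # (W', B, C')
        return y.transpose(1, 0, 2) + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(gout.transpose(1, 0, 2))  # (W', B, C')
        self.grads["w"] = self._pat.transpose(0, 2, 1) @ g
        self.grads["b"] = g.sum(axis=1)
        gp = (g @ self.params["w"].transpose(0, 2, 1)).transpose(1, 0, 2)
        return _scatter_patches(gp, self.k, self.c_in, self.w_in)


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch and width axes.

    Running statistics (exponential average, momentum 0.9) are used at
    inference so prediction is deterministic and batch-size independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._inv_std
            self._n = x.shape[0] * x.shape[1]
            return self.params["gamma"] * self._xhat + self.params["beta"]
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * (x - self.running_mean) * inv_std + self.params["beta"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        self.grads["gamma"] = (gout * xhat).sum(axis=(0, 1))
        self.grads["beta"] = gout.sum(axis=(0, 1))
        gxhat = gout * self.params["gamma"]
        return (inv_std / n) * (
            n * gxhat
            - gxhat.sum(axis=(0, 1))
            - xhat * (gxhat * xhat).sum(axis=(0, 1))
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along width; a trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def out_width(self, w: int) -> int:
        return w // self.pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, w, c = x.shape
        w_out = w // self.pool
        self._in_shape = x.shape
        xr = x[:, : w_out * self.pool, :].reshape(b, w_out, self.pool, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, w, c = self._in_shape
        w_out = gout.shape[1]
        gxr = np.zeros((b, w_out, self.pool, c), dtype=gout.dtype)
        np.put_along_axis(gxr, self._arg[:, :, None, :], gout[:, :, None, :], axis=2)
        gx = np.zeros((b, w, c), dtype=gout.dtype)
        gx[:, : w_out * self.pool, :] = gxr.reshape(b, w_out * self.pool, c)
        return gx


class AdaptiveAvgPool1d(Layer):
    """Average pooling into a fixed number of contiguous width bins.

    Bin i covers columns [floor(i*W/n), floor((i+1)*W/n)); bins tile the
    width exactly, so no column is dropped regardless of divisibility.
    """

    def __init__(self, out_width: int) -> None:
        super().__init__()
        self.n = out_width

    def out_width(self, w: int) -> int:
        if w < self.n:
            raise NetworkShapeError(f"cannot pool width {w} into {self.n} bins")
        return self.n

    def _edges(self, w: int) -> np.ndarray:
        return (np.arange(self.n + 1) * w) // self.n

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, w, c = x.shape
        self._w = w
        edges = self._edges(w)
        out = np.empty((b, self.n, c), dtype=x.dtype)
        for i in range(self.n):
            out[:, i, :] = x[:, edges[i]:edges[i + 1], :].mean(axis=1)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, _, c = gout.shape
        edges = self._edges(self._w)
        gx = np.empty((b, self._w, c), dtype=gout.dtype)
        for i in range(self.n):
            width = edges[i + 1] - edges[i]
            gx[:, edges[i]:edges[i + 1], :] = gout[:, i:i + 1, :] / width
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["w"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``v <- momentum * v - lr * g``, ``p <- p + v``. The learning rate is
    mutable so the training loop's halving schedule can act on it directly.
    """

    def __init__(self, layers: list[Layer], lr: float, momentum: float) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for key, p in layer.params.items():
                g = layer.grads[key].astype(np.float32)
                vel[key] = self.momentum * vel[key] - self.lr * g
                p += vel[key]
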