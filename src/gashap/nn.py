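"""Minimal 3D convolutional network engine in numpy.

Implements exactly the layer set the classifier architecture needs —
same-padding 3D convolution (im2col), ReLU, 2x2x2 max-pooling, inverted
dropout parameterized by *keep* probability, dense layers, softmax
cross-entropy — together with the Adadelta optimizer.  Forward and backward
passes are vectorized over the batch; the backward pass also yields the
gradient with respect to the input volume, which powers the gradient-based
attribution backend.

Tensors use the (N, C, D, H, W) layout in float32.  All randomness (weight
init, dropout, shuffling) flows through an explicit numpy Generator, so
training is bit-reproducible for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3D",
    "ReLU",
    "MaxPool3D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adadelta",
    "softmax",
    "softmax_cross_entropy",
]


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """Same-padding, stride-1 3D convolution with odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k**3
        self.params = {
            "W": rng.normal(0.0, _he_std(fan_in), size=(out_ch, in_ch, k, k, k)).astype(
                np.float32
            ),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._cache: tuple | None = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(N,C,D,H,W) -> (N*D*H*W, C*k^3) patch matrix, same padding."""
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # N,C,D,H,W,k,k,k
        n, c, d, h, w = x.shape
        return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * d * h * w, c * k**3
        )

    def forward(self, x, train, rng=None):
        n, c, d, h, w = x.shape
        cols = self._im2col(x, self.k)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.params["b"]
        out = out.reshape(n, d, h, w, self.out_ch).transpose(0, 4, 1, 2, 3)
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, d, h, w = xshape
        doutmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(
            n * d * h * w, self.out_ch
        )
        self.grads["W"][...] = (doutmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"][...] = doutmat.sum(axis=0)
        # dx: full correlation of dout with spatially flipped kernels, channels swapped
        wflip = self.params["W"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols2 = self._im2col(dout, self.k)
        dx = cols2 @ wflip.reshape(self.in_ch, -1).T
        return np.ascontiguousarray(dx.reshape(n, d, h, w, self.in_ch).transpose(0, 4, 1, 2, 3))


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; dims must be even."""

    def forward(self, x, train, rng=None):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2x2 pooling, got {x.shape}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        windows = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8
        )
        self._arg = windows.argmax(axis=-1)
        self._shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dout):
        n, c, d, h, w = self._shape
        dwin = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        return np.ascontiguousarray(dx.reshape(n, c, d, h, w))


class Dropout(Layer):
    """Inverted dropout with *keep* probability (identity in eval mode)."""

    def __init__(self, keep: float) -> None:
        super().__init__()
        if not 0.0 < keep <= 1.0:
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep
        self._mask: np.ndarray | None = None

    def forward(self, x, train, rng=None):
        if not train or self.keep >= 1.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an RNG"
        self._mask = (rng.random(x.shape) < self.keep).astype(x.dtype) / self.keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Affine layer; ``scale=0`` zero-initializes W (useful for the head)."""

    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, scale: float = 1.0
    ) -> None:
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, scale * _he_std(n_in), size=(n_in, n_out)).astype(
                np.float32
            ),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate to the input; fills each layer's ``grads``."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_state(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        pairs = self.parameters()
        if len(state) != len(pairs):
            raise ValueError("state does not match the network's parameter list")
        for (layer, name), value in zip(pairs, state):
            layer.params[name][...] = value


class Adadelta:
    """Adadelta with an explicit learning-rate multiplier.

    ``rho`` is the running-average decay of the squared-gradient and
    squared-update accumulators; ``lr`` scales the adaptive step.
    """

    def __init__(self, net: Sequential, lr: float = 0.05, rho: float = 0.95, eps: float = 1e-7):
        self.net, self.lr, self.rho, self.eps = net, lr, rho, eps
        self._Eg = [np.zeros_like(layer.params[n]) for layer, n in net.parameters()]
        self._Ed = [np.zeros_like(layer.params[n]) for layer, n in net.parameters()]

    def step(self) -> None:
        for (layer, name), eg, ed in zip(self.net.parameters(), self._Eg, self._Ed):
            g = layer.grads[name]
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * dx * dx
            layer.params[name] += self.lr * dx
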