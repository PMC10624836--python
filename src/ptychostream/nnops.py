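"""Minimal NumPy convolutional-network engine.

Exactly the pieces the phase-predicting surrogate needs, nothing more:
3x3 same-padding convolutions (im2col + BLAS matmul), ReLU, 2x2 max pooling,
nearest-neighbour upsampling, a bounded tanh output, the Adam optimizer, a
mean-absolute-error loss and a triangular cyclic learning-rate schedule.
All activations are float32 NHWC; parameter updates are deterministic given
the seeds fed to the callers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "ReLU", "MaxPool2", "Upsample2", "ScaledTanh",
           "Sequential", "Adam", "mae_loss_grad", "triangular_lr"]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = 9 * c_in
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # windows: (b, h, w, c, 3, 3) -> columns (b*h*w, 9*c)
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.reshape(b * h * w, c * 9).astype(np.float32, copy=True)
        self._cols, self._shape = cols, (b, h, w, c)
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dy_flat = dy.reshape(b * h * w, self.c_out).astype(np.float32)
        self.grads["W"] = self._cols.T @ dy_flat
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"].T).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, h + 2, w + 2, c), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[:, :, :, :, ki, kj]
        self._cols = None
        return dxp[:, 1:-1, 1:-1, :]

    @property
    def n_params(self) -> int:
        return self.params["W"].size + self.params["b"].size


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling; input sides must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = xr.reshape(b, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = (b, h, w, c)
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        flat = np.zeros((b, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None].astype(np.float32), axis=-1)
        return (flat.reshape(b, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3).reshape(b, h, w, c))


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling (checkerboard-safe with a following conv)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        return (dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
                .astype(np.float32))


class ScaledTanh(Layer):
    """tanh scaled by a constant; bounds the output to (-scale, scale)."""

    def __init__(self, scale: float) -> None:
        super().__init__()
        self.scale = float(scale)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = np.tanh(x)
        y = (self.scale * self._t).astype(np.float32)
        # float32 tanh saturates to exactly +-1; keep the interval open
        bound = np.float32(self.scale * (1.0 - 1e-7))
        return np.clip(y, -bound, bound)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self.scale * (1.0 - self._t ** 2)).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]

    def n_params(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [l.params[k].copy() for l, k in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (l, k), v in zip(self.parameters(), state):
            l.params[k] = v.copy()


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, net: Sequential, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in net.parameters()]
        self.v = [np.zeros_like(l.params[k]) for l, k in net.parameters()]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (l, k) in enumerate(self.net.parameters()):
            g = l.grads[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            l.params[k] = l.params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)


def mae_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient wrt the prediction."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(np.float32)
    return loss, grad


def triangular_lr(step: int, total_steps: int, lr_min: float, lr_max: float,
                  n_cycles: int = 1) -> float:
    """Triangular cyclic learning rate: lr_min -> lr_max -> lr_min per cycle."""
    if total_steps <= 1:
        return lr_max
    cycle_len = max(2, total_steps // n_cycles)
    pos = (step % cycle_len) / cycle_len  # in [0, 1)
    tri = 1.0 - abs(2.0 * pos - 1.0)      # 0 -> 1 -> 0
    return lr_min + (lr_max - lr_min) * tri
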