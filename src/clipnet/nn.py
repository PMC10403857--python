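"""Neural-network building blocks for the profile model.

Layers operate on tensors of shape ``(batch, length, channels)`` and are
implemented on top of the autodiff engine in :mod:`clipnet.autodiff`.  All
convolutions use same-padding and stride 1, so sequence length is preserved
end to end — the property that makes variable-length inference possible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Conv1D", "BatchNorm1D", "Dropout", "Dense", "Adam"]

_F32 = np.float32


class Layer:
    """Base class; subclasses populate ``params`` with trainable tensors."""

    def __init__(self):
        self.params: list[Tensor] = []

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params, arrays):
            p.data = np.asarray(a, dtype=p.data.dtype).copy()


class Conv1D(Layer):
    """1-D convolution with same padding, stride 1 and optional dilation.

    The kernel is stored as ``(width, in_channels, out_channels)`` and applied
    as a sum of shifted matrix products, which keeps the whole operation inside
    BLAS.  A transposed convolution with stride 1 is the cross-correlation with
    the flipped kernel, so the single-filter output heads reuse this layer.
    """

    def __init__(self, in_channels: int, out_channels: int, width: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        self.dilation = dilation
        rng = rng or np.random.default_rng()
        # He initialisation: fan_in = width * in_channels
        scale = np.sqrt(2.0 / (width * in_channels))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(width, in_channels, out_channels)).astype(_F32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=_F32), requires_grad=True)
        self.params = [self.weight, self.bias]
        # per-tap 2-D weight views rebuilt lazily each forward
        total = (width - 1) * dilation
        self._pad_left = total // 2
        self._pad_right = total - total // 2

    def __call__(self, x: Tensor) -> Tensor:
        # fused forward/backward as a single graph node: one pad, W in-place
        # accumulated matmuls, no per-tap intermediates
        B, L, Cin = x.shape
        W, d = self.width, self.dilation
        w_data, b_data = self.weight.data, self.bias.data
        Cout = w_data.shape[2]
        xp = np.pad(x.data, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        # float64 inputs (e.g. attribution graphs) keep float64 throughout
        out = np.zeros((B, L, Cout), dtype=np.result_type(x.data, w_data))
        out += b_data
        for w in range(W):
            seg = xp[:, w * d: w * d + L, :]
            np.add(out, seg @ w_data[w], out=out)

        pad_left = self._pad_left

        def backward(g):
            g2 = g.reshape(-1, Cout)
            gb = g2.sum(axis=0)
            gw = np.empty_like(w_data)
            gxp = np.zeros_like(xp)
            for w in range(W):
                seg = xp[:, w * d: w * d + L, :]
                gw[w] = seg.reshape(-1, Cin).T @ g2
                np.add(gxp[:, w * d: w * d + L, :], g @ w_data[w].T,
                       out=gxp[:, w * d: w * d + L, :])
            return gxp[:, pad_left: pad_left + L, :], gw, gb

        return Tensor._node(out, (x, self.weight, self.bias), backward)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)).astype(_F32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=_F32), requires_grad=True)
        self.params = [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm1D(Layer):
    """Batch normalisation over the channel axis of ``(B, L, C)`` tensors.

    Batch statistics are used in training; exponential running statistics at
    inference, which is what makes inference deterministic and well defined
    for a single window of arbitrary length.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=_F32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=_F32), requires_grad=True)
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=1, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True).mean(
                axis=1, keepdims=True
            )
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(_F32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(_F32)
            inv_std = (var + self.eps).power(-0.5)
            return centred * inv_std * self.gamma + self.beta
        inv_std = (self.running_var + self.eps) ** -0.5
        return (x - Tensor(self.running_mean)) * Tensor(inv_std) * self.gamma + self.beta

    def state(self):
        return super().state() + [self.running_mean.copy(), self.running_var.copy()]

    def load_state(self, arrays):
        super().load_state(arrays[:2])
        self.running_mean = np.asarray(arrays[2], dtype=_F32).copy()
        self.running_var = np.asarray(arrays[3], dtype=_F32).copy()


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 0.004,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data = p.data - lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
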