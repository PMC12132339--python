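"""Minimal fully-convolutional network in numpy for heatmap regression.

Implements just what the behavior detector needs: 3x3 convolutions via
im2col, ReLU, nearest-neighbor 2x upsampling, a sigmoid head trained with
(optionally positive-weighted) binary cross-entropy or MSE, and Adam.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """x (B,C,H,W) -> columns (B, C*k*k, Ho*Wo)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add column gradients back to the input."""
    b, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(b, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += d[:, :, ki, kj]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator, k: int = 3):
        self.k, self.stride, self.pad = k, stride, k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.w = rng.normal(0.0, scale, (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,bcl->bol", self.w, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        b = dout.shape[0]
        dflat = dout.reshape(b, -1, ho * wo)
        self.dw = np.einsum("bol,bcl->oc", dflat, cols)
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.w, dflat)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []


class Upsample2:
    """Nearest-neighbor 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    params: list = []


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    state: dict = field(default_factory=dict)

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for name, p in layer.params:
                g = getattr(layer, "d" + name)
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class HeatmapNet:
    """Encoder (stride-2 conv blocks) + three upsampling stages + sigmoid head.

    With the default strides (2, 2, 2, 1) the three 2x upsampling stages
    bring the output back to input resolution (output stride 1).
    """

    def __init__(
        self,
        n_classes: int = 1,
        encoder_channels: tuple[int, ...] = (8, 16, 16, 16),
        encoder_strides: tuple[int, ...] = (2, 2, 2, 1),
        decoder_channels: tuple[int, ...] = (16, 8),
        seed: int = 0,
    ):
        if len(encoder_channels) != len(encoder_strides):
            raise ValueError("encoder_channels and encoder_strides must match")
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c = 1
        for ch, s in zip(encoder_channels, encoder_strides):
            self.layers.append(Conv2d(c, ch, s, rng))
            self.layers.append(ReLU())
            c = ch
        for ch in decoder_channels:  # first two upsampling stages
            self.layers.append(Upsample2())
            self.layers.append(Conv2d(c, ch, 1, rng))
            self.layers.append(ReLU())
            c = ch
        self.layers.append(Upsample2())  # third upsampling stage + head
        self.layers.append(Conv2d(c, n_classes, 1, rng))
        down = int(np.prod(encoder_strides))
        self.output_stride = max(down // 8, 1)
        self.n_classes = n_classes

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x (B,H,W) or (B,1,H,W) -> sigmoid heatmaps (B,C,H/stride,W/stride)."""
        if x.ndim == 3:
            x = x[:, None]
        out = x.astype(float)
        for layer in self.layers:
            out = layer.forward(out)
        return 1.0 / (1.0 + np.exp(-out))

    def _forward_logits(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        out = x.astype(float)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def train_batch(self, x, y, opt: Adam, loss: str = "bce", pos_weight: float = 20.0) -> float:
        """One optimizer step; returns the batch loss."""
        logits = self._forward_logits(x)
        p = 1.0 / (1.0 + np.exp(-logits))
        w = 1.0 + (pos_weight - 1.0) * y
        n = y.size
        if loss == "bce":
            eps = 1e-12
            val = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).sum() / n
            dlogits = w * (p - y) / n
        elif loss == "mse":
            val = (w * (p - y) ** 2).sum() / n
            dlogits = 2 * w * (p - y) * p * (1 - p) / n
        else:
            raise ValueError(f"unknown loss '{loss}'")
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        opt.step(self.layers)
        return float(val)
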