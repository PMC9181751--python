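"""Minimal numpy CNN engine: layers with explicit forward/backward passes.

Supports exactly what the thickness regressor needs — 3x3 "same"
convolutions (stride 1 or 2) via im2col, ReLU, 2x2 max pooling, flatten and
a dense head — plus Glorot/Xavier initialisation.  Arrays are NCHW float64;
gradients are computed analytically layer by layer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Sequential", "xavier_uniform"]


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter-less unless overridden."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    # weight-decay applies to these (weights, not biases)
    def decayed(self) -> tuple[str, ...]:
        return ()


class Conv2D(Layer):
    """3x3 (k x k) convolution, zero 'same' padding, stride 1 or 2.

    ``init="xavier_improved"`` (the ReLU-corrected Glorot variant,
    W ~ N(0, 2/fan_in)) keeps activation scale roughly constant through a
    deep ReLU stack; plain ``"xavier"`` attenuates it by ~0.7 per layer.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator,
                 init: str = "xavier_improved") -> None:
        super().__init__()
        k = kernel_size
        self.k, self.stride, self.pad = k, stride, k // 2
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        shape = (out_channels, in_channels, k, k)
        if init == "xavier_improved":
            weights = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        elif init == "xavier":
            weights = xavier_uniform(rng, shape, fan_in, fan_out)
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params = {"W": weights, "b": np.zeros(out_channels)}

    def decayed(self) -> tuple[str, ...]:
        return ("W",)

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        s = self.stride
        return ((h + 2 * self.pad - self.k) // s + 1,
                (w + 2 * self.pad - self.k) // s + 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        Ho, Wo = self.out_hw(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        wmat = self.params["W"].reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (x.shape, cols)
        return out.reshape(B, Ho, Wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, C, H, W), cols = self._cache
        k, s, p = self.k, self.stride, self.pad
        Bo, Co, Ho, Wo = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(B, Ho * Wo, Co)
        wmat = self.params["W"].reshape(Co, -1)
        self.grads["W"] = np.einsum("bpc,bpk->ck", dmat, cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=(0, 1))
        dcols = dmat @ wmat  # (B, Ho*Wo, C*k*k)
        d6 = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * (Ho - 1) + 1:s, j:j + s * (Wo - 1) + 1:s] += d6[:, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, :2 * H2, :2 * W2]
        win = xc.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = (B, C, H, W)
        return win.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        dwin = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, C, H, W))
        dx[:, :, :2 * H2, :2 * W2] = (
            dwin.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, 2 * H2, 2 * W2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": xavier_uniform(rng, (in_features, out_features), in_features, out_features),
            "b": np.zeros(out_features),
        }

    def decayed(self) -> tuple[str, ...]:
        return ("W",)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """Ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                out[f"layer{i}.{name}"] = value
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.grads.items():
                out[f"layer{i}.{name}"] = value
        return out

    def decayed_names(self) -> set[str]:
        names = set()
        for i, layer in enumerate(self.layers):
            for name in layer.decayed():
                names.add(f"layer{i}.{name}")
        return names

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        if set(values) != set(own):
            raise ValueError("parameter name mismatch when loading weights")
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(values[f"layer{i}.{name}"], dtype=float)
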