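"""Minimal NumPy neural-network layers with manual reverse-mode gradients.

Every layer exposes ``forward(x, train)`` (caching what the backward pass
needs), ``backward(dout)`` (returning the input gradient and accumulating
parameter gradients in ``grads``), and dict-style parameter access for
optimizers and checkpointing. Convolutions use im2col over
``sliding_window_view`` so the heavy lifting is a single einsum; transposed
convolutions and the pooling/normalization layers are written as explicit
adjoints of their forward maps, which keeps gradients exact and fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _he_init(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """Valid (no padding) strided 2-D convolution, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.s = kernel, stride
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.k, self.s
        if x.shape[2] < k or x.shape[3] < k:
            raise ValueError(f"input {x.shape[2:]} smaller than kernel {k}")
        cols = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._cache = (x.shape, cols)
        out = np.einsum("bchwij,ocij->bohw", cols, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        k, s = self.k, self.s
        self.grads["W"] += np.einsum("bohw,bchwij->ocij", dout, cols, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dcols = np.einsum("bohw,ocij->bchwij", dout, self.params["W"], optimize=True)
        dx = np.zeros(x_shape)
        ho, wo = dout.shape[2], dout.shape[3]
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += dcols[..., i, j]
        return dx


class ConvTranspose2d(Layer):
    """Strided transposed convolution; output size (H-1)*stride + kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.s = kernel, stride
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _he_init(rng, (in_ch, out_ch, kernel, kernel), fan_in),
            "b": np.zeros(out_ch),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _out_hw(self, hi: int, wi: int) -> Tuple[int, int]:
        return (hi - 1) * self.s + self.k, (wi - 1) * self.s + self.k

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, hi, wi = x.shape
        ho, wo = self._out_hw(hi, wi)
        self._cache = x
        w = self.params["W"]
        out = np.zeros((b, w.shape[1], ho, wo))
        for i in range(self.k):
            for j in range(self.k):
                out[:, :, i : i + self.s * (hi - 1) + 1 : self.s,
                    j : j + self.s * (wi - 1) + 1 : self.s] += np.einsum(
                        "bchw,co->bohw", x, w[:, :, i, j], optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        b, c, hi, wi = x.shape
        w = self.params["W"]
        dx = np.zeros_like(x)
        for i in range(self.k):
            for j in range(self.k):
                sl = dout[:, :, i : i + self.s * (hi - 1) + 1 : self.s,
                          j : j + self.s * (wi - 1) + 1 : self.s]
                dx += np.einsum("bohw,co->bchw", sl, w[:, :, i, j], optimize=True)
                self.grads["W"][:, :, i, j] += np.einsum("bchw,bohw->co", x, sl, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        return dx


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _he_init(rng, (in_dim, out_dim), in_dim), "b": np.zeros(out_dim)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"] += x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.update_stats = True  # disabled during gradient-penalty re-passes

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.update_stats:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None] / std[None, :, None, None]
        if not train:
            return dout * g
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        sum_d = dout.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        sum_dx = (dout * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        return g * (dout - sum_d / m - xhat * sum_dx / m)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._out**2)


class MaxPool2d(Layer):
    """Non-overlapping k x k max pooling with floor semantics."""

    def __init__(self, kernel: int) -> None:
        super().__init__()
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.k == 1:
            self._cache = None
            return x
        b, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} smaller than pool {k}")
        xc = x[:, :, : ho * k, : wo * k]
        xr = xc.reshape(b, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, k * k)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.k == 1 or self._cache is None:
            return dout
        idx, x_shape = self._cache
        b, c, h, w = x_shape
        k = self.k
        ho, wo = h // k, w // k
        dxr = np.zeros((b, c, ho, wo, k * k))
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, : ho * k, : wo * k] = dxr.reshape(b, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho * k, wo * k)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid using torch-style segment bounds."""

    def __init__(self, out_hw: Tuple[int, int]) -> None:
        super().__init__()
        self.oh, self.ow = out_hw

    @staticmethod
    def _bounds(n: int, out: int) -> List[Tuple[int, int]]:
        return [(math.floor(i * n / out), math.ceil((i + 1) * n / out)) for i in range(out)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        hb, wb = self._bounds(h, self.oh), self._bounds(w, self.ow)
        self._cache = (x.shape, hb, wb)
        out = np.empty((b, c, self.oh, self.ow))
        for a, (h0, h1) in enumerate(hb):
            for d, (w0, w1) in enumerate(wb):
                out[:, :, a, d] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, hb, wb = self._cache
        dx = np.zeros(x_shape)
        for a, (h0, h1) in enumerate(hb):
            for d, (w0, w1) in enumerate(wb):
                dx[:, :, h0:h1, w0:w1] += dout[:, :, a : a + 1, d : d + 1] / ((h1 - h0) * (w1 - w0))
        return dx


class Dropout(Layer):
    """Inverted dropout. ``reuse_mask`` replays the previous mask, which the
    gradient-penalty finite-difference passes need for consistency."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p, self.rng = p, rng
        self.reuse_mask = False
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._train = False
            return x
        self._train = True
        if not (self.reuse_mask and self._mask is not None and self._mask.shape == x.shape):
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask if self._train else dout


class Flatten(Layer):
    """Flatten NCHW to (N, C*H*W); records the flattened width."""

    last_width: Optional[int] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        self.last_width = int(np.prod(x.shape[1:]))
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class BilinearResize(Layer):
    """Deterministic bilinear resize as two precomputed interpolation
    matrices; exactly linear, so the backward pass is the transpose map."""

    def __init__(self, in_hw: Tuple[int, int], out_hw: Tuple[int, int]) -> None:
        super().__init__()
        self.A = self._matrix(in_hw[0], out_hw[0])
        self.B = self._matrix(in_hw[1], out_hw[1])

    @staticmethod
    def _matrix(n_in: int, n_out: int) -> np.ndarray:
        m = np.zeros((n_out, n_in))
        for i in range(n_out):
            src = (i + 0.5) * n_in / n_out - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            lo = int(math.floor(src))
            hi = min(lo + 1, n_in - 1)
            w = src - lo
            m[i, lo] += 1.0 - w
            m[i, hi] += w
        return m

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.einsum("oh,bchw,pw->bcop", self.A, x, self.B, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.einsum("oh,bcop,pw->bchw", self.A, dout, self.B, optimize=True)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self):
        for k, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"layer{k}.{name}", p, layer.grads[name]

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.copy() for name, p, _ in self.named_params()}
        for k, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"layer{k}.running_mean"] = layer.running_mean.copy()
                state[f"layer{k}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, p, _ in self.named_params():
            p[...] = state[name]
        for k, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{k}.running_mean"]
                layer.running_var[...] = state[f"layer{k}.running_var"]

    def set_update_stats(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.update_stats = flag

    def set_reuse_dropout(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.reuse_mask = flag
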