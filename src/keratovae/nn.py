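"""Minimal layer/backprop engine used by the VAE and the CNN classifiers.

Layers operate on channels-last float32 tensors ``(N, H, W, C)``.  Stride-2
convolutions use "same" padding with ceiling division (out = ceil(in / s),
TensorFlow convention: the extra pad pixel goes on the bottom/right), which
is what makes the documented shape chains close (104 -> 52 -> 26 -> 13,
50 -> 25 -> 13 -> 7).  ``ConvTranspose2D`` is implemented as the exact
adjoint of that convolution, so a stride-2 transposed conv maps H -> 2H.

Every layer exposes ``forward`` / ``backward`` and its ``(param, grad)``
pairs; gradients are checked against numerical differentiation in the test
suite.  All randomness (init, dropout) flows through explicit
``numpy.random.Generator`` objects for reproducibility.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Layer", "Conv2D", "ConvTranspose2D", "Dense", "Flatten", "Reshape",
    "ReLU", "Sigmoid", "Dropout", "GlobalAvgPool", "Rescale", "Sequential",
    "RMSprop", "Adam", "make_optimizer", "bce", "bce_grad",
]


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Strided patch extraction on a padded input -> (N, ho, wo, k*k*C).

    Patch layout is (kh, kw, C); built with one slice per kernel offset,
    which beats a sliding-window copy on stride-2 inputs."""
    n, _, _, c = xp.shape
    cols = np.empty((n, ho, wo, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i:i + s * ho:s, j:j + s * wo:s, :]
    return cols.reshape(n, ho, wo, k * k * c)


def _col2im(dcols: np.ndarray, xp_shape, k: int, s: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the grid."""
    n, hp, wp, c = xp_shape
    _, ho, wo, _ = dcols.shape
    d = dcols.reshape(n, ho, wo, k, k, c)
    out = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, i:i + s * ho:s, j:j + s * wo:s, :] += d[:, :, :, i, j, :]
    return out


class Layer:
    name = "layer"

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape


class Conv2D(Layer):
    """3x3 (by default) convolution, same-ceil padding, stride 1 or 2."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.name = name

    def forward(self, x, training=False, rng=None):
        n, h, w, _ = x.shape
        if self.k == 1 and self.stride == 1:  # pointwise: no patch extraction
            self._cache = (x, None, None)
            return x @ self.w + self.b
        ho, pt, pb = _same_pad(h, self.k, self.stride)
        wo, pl, pr = _same_pad(w, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, self.k, self.stride, ho, wo)
        self._cache = (cols, xp.shape, (h, w, pt, pl))
        return cols @ self.w + self.b

    def backward(self, dy):
        cols, xp_shape, geom = self._cache
        dyf = dy.reshape(-1, self.out_ch)
        self.dw[...] = cols.reshape(-1, cols.shape[-1]).T @ dyf
        self.db[...] = dyf.sum(axis=0)
        if self.k == 1 and self.stride == 1:
            return dy @ self.w.T
        h, w, pt, pl = geom
        dcols = dy @ self.w.T
        dxp = _col2im(dcols, xp_shape, self.k, self.stride)
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        return (-(-h // self.stride), -(-w // self.stride), self.out_ch)


class ConvTranspose2D(Layer):
    """Adjoint of the same-ceil stride-s conv: maps (H, W) -> (sH, sW)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None, name: str = "convT"):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        fan_in = out_ch * k * k  # weight layout mirrors the adjoint conv
        self.w = (rng.standard_normal((fan_in, in_ch)) * np.sqrt(2.0 / (in_ch * k * k))).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.name = name

    def _geometry(self, h: int, w: int):
        ho, wo = h * self.stride, w * self.stride
        _, pt, pb = _same_pad(ho, self.k, self.stride)
        _, pl, pr = _same_pad(wo, self.k, self.stride)
        return ho, wo, pt, pb, pl, pr

    def forward(self, x, training=False, rng=None):
        n, h, w, _ = x.shape
        ho, wo, pt, pb, pl, pr = self._geometry(h, w)
        xp_shape = (n, ho + pt + pb, wo + pl + pr, self.out_ch)
        dcols = x @ self.w.T  # (N, h, w, out_ch*k*k)
        yp = _col2im(dcols, xp_shape, self.k, self.stride)
        y = yp[:, pt:pt + ho, pl:pl + wo, :] + self.b
        self._cache = (x, (h, w))
        return y

    def backward(self, dy):
        x, (h, w) = self._cache
        n = dy.shape[0]
        ho, wo, pt, pb, pl, pr = self._geometry(h, w)
        dyp = np.pad(dy, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(dyp, self.k, self.stride, h, w)
        self.db[...] = dy.sum(axis=(0, 1, 2))
        self.dw[...] = cols.reshape(-1, cols.shape[-1]).T @ x.reshape(-1, self.in_ch)
        return cols @ self.w

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        return (h * self.stride, w * self.stride, self.out_ch)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def out_shape(self, in_shape):
        return (self.w.shape[1],)


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Reshape(Layer):
    def __init__(self, shape: tuple, name: str = "reshape"):
        self.shape = tuple(shape)
        self.name = name

    def forward(self, x, training=False, rng=None):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)

    def out_shape(self, in_shape):
        return self.shape


class ReLU(Layer):
    name = "relu"

    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    name = "sigmoid"

    def forward(self, x, training=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    name = "gap"

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).copy()

    def out_shape(self, in_shape):
        return (in_shape[2],)


class Rescale(Layer):
    """Affine range map y = a*x + b (e.g. [0,1] -> [-1,1] with a=2, b=-1)."""

    def __init__(self, a: float, b: float, name: str = "rescale"):
        self.a, self.b = a, b
        self.name = name

    def forward(self, x, training=False, rng=None):
        return self.a * x + self.b

    def backward(self, dy):
        return self.a * dy


class Sequential:
    def __init__(self, layers: Sequence[Layer], input_shape: tuple | None = None):
        self.layers = list(layers)
        self.input_shape = input_shape

    def forward(self, x, training=False, rng=None, until: str | None = None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
            if until is not None and layer.name == until:
                break
        return x

    __call__ = forward

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def summary(self) -> list[dict]:
        """Per-layer output shapes and parameter counts (needs input_shape)."""
        if self.input_shape is None:
            raise ValueError("summary requires input_shape")
        shape = tuple(self.input_shape)
        rows = []
        for layer in self.layers:
            shape = layer.out_shape(shape)
            n_par = sum(int(p.size) for p, _ in layer.params())
            rows.append({"layer": layer.name, "output_shape": tuple(shape),
                         "n_params": n_par})
        return rows

    # --- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, (p, _) in enumerate(layer.params()):
                state[f"{i}_{layer.name}_{j}"] = p
        return state

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            for key, p in self.state_dict().items():
                p[...] = data[key]

    def checksum(self) -> dict[str, float]:
        """Per-layer parameter checksums (bitwise-change detector)."""
        import zlib

        out = {}
        for i, layer in enumerate(self.layers):
            if layer.params():
                blob = b"".join(np.ascontiguousarray(p).tobytes() for p, _ in layer.params())
                out[f"{i}_{layer.name}"] = zlib.crc32(blob)
        return out


# --- optimizers -----------------------------------------------------------

class RMSprop:
    def __init__(self, params: Iterable[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        self.pairs = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self):
        for (p, g), v in zip(self.pairs, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam:
    def __init__(self, params: Iterable[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-4, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-7):
        self.pairs = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def make_optimizer(name: str, params, lr: float):
    if name in ("rmsprop", "rms"):
        return RMSprop(params, lr=lr)
    if name == "adam":
        return Adam(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


# --- losses ---------------------------------------------------------------

_EPS = 1e-7


def bce(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities ``p`` against labels ``y``."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return (p - y) / (p * (1.0 - p)) / p.shape[0]
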