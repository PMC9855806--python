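"""Minimal NumPy neural-network layers for the pocket classifier.

Implements exactly the operations the classifier architecture needs --
3-D convolution (kernel 2, stride 1, optional total padding), batch
normalization, ReLU, 2x2x2 max pooling, dropout, dense layers and a sigmoid
head -- with hand-written backpropagation and plain SGD.  Convolutions use
an im2col layout so the heavy lifting is BLAS matrix products in float32.

All randomness (weight init, shuffling, dropout) flows through
``numpy.random.Generator`` objects supplied by the caller, so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

F4 = np.float32


class Layer:
    """Base class: stateless unless it declares params/grads."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays to persist (parameters plus any running statistics)."""
        return self.params

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), arrays):
            dst[...] = src


_OFFSETS = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)]


class Conv3d(Layer):
    """3-D convolution, kernel 2x2x2, stride 1.

    ``pad`` is the *total* zero padding added per spatial axis: 0 keeps the
    valid convolution (output size n-1), 2 pads one plane on each side
    (output size n+1).  Weights use He fan-in initialization.
    """

    def __init__(self, cin: int, cout: int, pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        if pad not in (0, 1, 2):
            raise ValueError("pad must be 0, 1 or 2")
        self.cin, self.cout, self.pad = cin, cout, pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * 8))
        self.W = rng.normal(0.0, scale, size=(cout, cin * 8)).astype(F4)
        self.b = np.zeros(cout, dtype=F4)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_size(self, n: int) -> int:
        return n + self.pad - 1

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x
        left = self.pad // 2
        right = self.pad - left
        return np.pad(x, ((0, 0), (0, 0)) + ((left, right),) * 3)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = self._pad(x.astype(F4, copy=False))
        b, c = xp.shape[:2]
        od = xp.shape[2] - 1
        if od < 1:
            raise ValueError("spatial size underflow in convolution")
        cols = np.empty((b, c, 8, od, od, od), dtype=F4)
        for m, (i, j, k) in enumerate(_OFFSETS):
            cols[:, :, m] = xp[:, :, i : i + od, j : j + od, k : k + od]
        cols2 = cols.reshape(b, c * 8, od**3)
        out = np.matmul(self.W, cols2) + self.b[:, None]
        self._cache = (cols2, x.shape, xp.shape)
        return out.reshape(b, self.cout, od, od, od)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols2, x_shape, xp_shape = self._cache
        b = gy.shape[0]
        od = gy.shape[2]
        g = gy.reshape(b, self.cout, od**3).astype(F4, copy=False)
        self.grads[0][...] = np.matmul(g, cols2.transpose(0, 2, 1)).sum(axis=0)
        self.grads[1][...] = g.sum(axis=(0, 2))
        gcols = np.matmul(self.W.T, g).reshape(b, self.cin, 8, od, od, od)
        gxp = np.zeros(xp_shape, dtype=F4)
        for m, (i, j, k) in enumerate(_OFFSETS):
            gxp[:, :, i : i + od, j : j + od, k : k + od] += gcols[:, :, m]
        if self.pad:
            left = self.pad // 2
            d = x_shape[2]
            gxp = gxp[:, :, left : left + d, left : left + d, left : left + d]
        return gxp


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis.

    ``spatial=True`` treats input as (B, C, D, H, W); otherwise (B, C).
    Uses biased batch variance in training and exponential running
    statistics (momentum 0.1) at evaluation time.
    """

    def __init__(self, channels: int, spatial: bool, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.spatial = spatial
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=F4)
        self.beta = np.zeros(channels, dtype=F4)
        self.running_mean = np.zeros(channels, dtype=F4)
        self.running_var = np.ones(channels, dtype=F4)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0, 2, 3, 4) if x.ndim == 5 else (0,)

    def _shape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, -1, 1, 1, 1) if x.ndim == 5 else (1, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = x.astype(F4, copy=False)
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes, shp = self._axes(gy), self._shape(gy)
        m = gy.size // gy.shape[1]
        self.grads[0][...] = (gy * xhat).sum(axis=axes)
        self.grads[1][...] = gy.sum(axis=axes)
        gxhat = gy * self.gamma.reshape(shp)
        mean_g = gxhat.sum(axis=axes, keepdims=True) / m
        mean_gx = (gxhat * xhat).sum(axis=axes, keepdims=True) / m
        return inv.reshape(shp) * (gxhat - mean_g - xhat * mean_gx)

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (odd trailing planes are dropped).

    The gradient is routed to a single (first) maximum per window so tied
    values -- common after ReLU zero plateaus -- are not double-counted.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xr = x[:, :, : d2 * 2, : h2 * 2, : w2 * 2].reshape(b, c, d2, 2, h2, 2, w2, 2)
        xt = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            b, c, d2, h2, w2, 8
        )
        arg = xt.argmax(axis=-1)
        out = np.take_along_axis(xt, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, arg = self._cache
        b, c, d, h, w = x_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        g8 = np.zeros((b, c, d2, h2, w2, 8), dtype=F4)
        np.put_along_axis(g8, arg[..., None], gy[..., None].astype(F4), axis=-1)
        g_crop = g8.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros(x_shape, dtype=F4)
        gx[:, :, : d2 * 2, : h2 * 2, : w2 * 2] = g_crop.reshape(
            b, c, d2 * 2, h2 * 2, w2 * 2
        )
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / nin)
        self.W = rng.normal(0.0, scale, size=(nout, nin)).astype(F4)
        self.b = np.zeros(nout, dtype=F4)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x.astype(F4, copy=False)
        return self._x @ self.W.T + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = gy.astype(F4, copy=False)
        self.grads[0][...] = gy.T @ self._x
        self.grads[1][...] = gy.sum(axis=0)
        return gy @ self.W


class Dropout(Layer):
    """Inverted dropout; the RNG is shared model state set by the trainer."""

    def __init__(self, p: float, rng_holder: dict):
        super().__init__()
        self.p = p
        self._rng_holder = rng_holder

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        rng = self._rng_holder["rng"]
        self._mask = (rng.random(x.shape) >= self.p).astype(F4) / F4(1 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._y * (1 - self._y)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=F4)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ArchSpec:
    """Architecture hyperparameters of the pocket classifier."""

    input_points_per_edge: int
    output_dim: int
    in_channels: int = 4
    conv_channels: tuple[int, int, int] = (64, 128, 128)
    conv_pads: tuple[int, int, int] = (0, 2, 0)
    dense_units: tuple[int, int] = (128, 64)
    dropout: float = 0.4

    def spatial_sizes(self) -> list[int]:
        """Spatial extent after each convolution and the pooling layer."""
        n = self.input_points_per_edge
        sizes = []
        for pad in self.conv_pads:
            n = n + pad - 1
            if n < 1:
                raise ValueError("spatial size underflow for this input size")
            sizes.append(n)
        sizes.append(n // 2)
        return sizes

    def flatten_width(self) -> int:
        return self.conv_channels[-1] * self.spatial_sizes()[-1] ** 3


class Network:
    """A feed-forward stack of layers ending in a sigmoid head."""

    def __init__(self, spec: ArchSpec, layers: list[Layer], rng_holder: dict):
        self.spec = spec
        self.layers = layers
        self._rng_holder = rng_holder

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        self._rng_holder["rng"] = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x, train)
        return x

    def backward_from_logits(self, gz: np.ndarray) -> None:
        g = gz
        for layer in reversed(self.layers[:-1]):
            g = layer.backward(g)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                p -= F4(lr) * g

    def state_arrays(self) -> list[np.ndarray]:
        return [a for layer in self.layers for a in layer.state_arrays()]

    def save(self, path: str | Path) -> None:
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        meta = {
            "input_points_per_edge": self.spec.input_points_per_edge,
            "output_dim": self.spec.output_dim,
            "in_channels": self.spec.in_channels,
            "conv_channels": list(self.spec.conv_channels),
            "conv_pads": list(self.spec.conv_pads),
            "dense_units": list(self.spec.dense_units),
            "dropout": self.spec.dropout,
        }
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        spec = ArchSpec(
            input_points_per_edge=meta["input_points_per_edge"],
            output_dim=meta["output_dim"],
            in_channels=meta["in_channels"],
            conv_channels=tuple(meta["conv_channels"]),
            conv_pads=tuple(meta["conv_pads"]),
            dense_units=tuple(meta["dense_units"]),
            dropout=meta["dropout"],
        )
        net = build_network(spec.input_points_per_edge, spec.output_dim, seed=0,
                            conv_channels=spec.conv_channels, dense_units=spec.dense_units,
                            dropout=spec.dropout)
        arrays = [data[f"a{i}"].copy() for i in range(len(net.state_arrays()))]
        pos = 0
        for layer in net.layers:
            k = len(layer.state_arrays())
            layer.load_state(arrays[pos : pos + k])
            pos += k
        return net


def build_network(
    input_points_per_edge: int,
    output_dim: int,
    seed: int = 0,
    conv_channels: tuple[int, int, int] = (64, 128, 128),
    dense_units: tuple[int, int] = (128, 64),
    dropout: float = 0.4,
) -> Network:
    """Assemble the pocket classifier.

    Layer stack: Conv(2^3, valid) -> Conv(2^3, padded) -> BatchNorm ->
    Conv(2^3, valid) -> ReLU -> BatchNorm -> MaxPool(2, stride 2) ->
    Flatten -> Dense -> ReLU -> Dropout -> Dense -> BatchNorm -> ReLU ->
    Dense(output_dim) -> Sigmoid.  With a 22-point input edge and the
    default channel widths the flattened width is 128 * 10^3 = 128,000.
    """
    if input_points_per_edge < 8:
        raise ValueError("input_points_per_edge must be >= 8")
    if output_dim not in (2, 3):
        raise ValueError("output_dim must be 2 or 3")
    spec = ArchSpec(
        input_points_per_edge=input_points_per_edge,
        output_dim=output_dim,
        conv_channels=conv_channels,
        dense_units=dense_units,
        dropout=dropout,
    )
    rng = np.random.default_rng(seed)
    holder: dict = {"rng": np.random.default_rng(rng.integers(2**31))}
    c1, c2, c3 = conv_channels
    d1, d2 = dense_units
    layers: list[Layer] = [
        Conv3d(spec.in_channels, c1, pad=spec.conv_pads[0], rng=rng),
        Conv3d(c1, c2, pad=spec.conv_pads[1], rng=rng),
        BatchNorm(c2, spatial=True),
        Conv3d(c2, c3, pad=spec.conv_pads[2], rng=rng),
        ReLU(),
        BatchNorm(c3, spatial=True),
        MaxPool3d(),
        Flatten(),
        Linear(spec.flatten_width(), d1, rng=rng),
        ReLU(),
        Dropout(dropout, holder),
        Linear(d1, d2, rng=rng),
        BatchNorm(d2, spatial=False),
        ReLU(),
        Linear(d2, output_dim, rng=rng),
        Sigmoid(),
    ]
    return Network(spec, layers, holder)


def bce_loss_and_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy summed over labels, averaged over the batch.

    Computed from logits for numerical stability; the returned gradient is
    with respect to the logits.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # log(1 + exp(-|z|)) formulation
    per_elem = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(per_elem.sum(axis=1).mean())
    p = sigmoid(logits.astype(F4)).astype(np.float64)
    grad = ((p - y) / z.shape[0]).astype(F4)
    return loss, grad
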