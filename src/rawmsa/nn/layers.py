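"""Neural-network layers built on the autograd engine.

Conventions: alignment-window tensors are (batch, width, depth, channels),
pair tensors are (batch, L, L, channels). Convolutions over alignments act
only along the depth axis (one filter column per sequence position), so
information never leaks between residue positions before the recurrent or
pair stages.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Embedding",
    "ColumnConvPool",
    "BiLSTM",
    "Dense",
    "Dropout",
    "Conv2dSame",
    "BatchNorm",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Base class; collects parameters from Tensor/Module/list attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for name in sorted(vars(self)):
            params.extend(_collect(getattr(self, name)))
        return params

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(obj) -> list[Tensor]:
    if isinstance(obj, Tensor) and obj.requires_grad:
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out: list[Tensor] = []
        for item in obj:
            out.extend(_collect(item))
        return out
    return []


class Embedding(Module):
    """Learned lookup from integer symbol indices to E-dimensional vectors.

    Index 0 (the zero-padding symbol) owns a learnable row like every other
    symbol; padding neutrality is guaranteed upstream by reserving 0 for
    padding only, never for residues.
    """

    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator):
        self.n_symbols = n_symbols
        self.dim = dim
        self.weight = _glorot(rng, (n_symbols, dim), n_symbols, dim)

    def forward(self, indices: np.ndarray) -> Tensor:
        indices = np.asarray(indices)
        if indices.min() < 0 or indices.max() >= self.n_symbols:
            raise ValueError(
                f"symbol index outside vocabulary range 0..{self.n_symbols - 1}"
            )
        return self.weight.take_rows(indices)


class ColumnConvPool(Module):
    """Column-wise convolution + max pooling along the alignment depth.

    Filters are 1 x `kernel` column vectors (never square), applied with
    zero padding so the depth is preserved, then max-pooled in windows of
    `pool` with stride `pool` (floor remainder). ReLU activation.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: int,
        pool: int,
        rng: np.random.Generator,
    ):
        if kernel < 1 or pool < 1 or filters < 1:
            raise ValueError("kernel, pool and filters must be positive")
        self.kernel = kernel
        self.pool = pool
        self.filters = filters
        self.weight = _glorot(
            rng, (kernel, in_channels, filters), kernel * in_channels, filters
        )
        self.bias = Tensor(np.zeros(filters), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        depth = x.shape[2]
        if depth < self.pool:
            raise ValueError(f"alignment depth {depth} is smaller than pool window {self.pool}")
        before = (self.kernel - 1) // 2
        after = self.kernel // 2
        xp = x.pad_axis(2, before, after)
        acc = None
        for o in range(self.kernel):
            term = xp[:, :, o : o + depth, :] @ self.weight[o]
            acc = term if acc is None else acc + term
        out = (acc + self.bias).relu()
        pooled_depth = depth // self.pool
        out = out[:, :, : pooled_depth * self.pool, :]
        out = out.reshape(
            x.shape[0], x.shape[1], pooled_depth, self.pool, self.filters
        )
        return out.max(axis=3)


class _LSTMDirection(Module):
    def __init__(self, in_size: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = _glorot(rng, (in_size, 4 * hidden), in_size, 4 * hidden)
        self.wh = _glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden)
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias starts open
        self.bias = Tensor(bias, requires_grad=True)

    def forward(self, x: Tensor, reverse: bool) -> list[Tensor]:
        batch, steps, _ = x.shape
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        order = range(steps - 1, -1, -1) if reverse else range(steps)
        outputs: list[Tensor | None] = [None] * steps
        n = self.hidden
        for t in order:
            z = x[:, t, :] @ self.wx + h @ self.wh + self.bias
            i = z[:, 0:n].sigmoid()
            f = z[:, n : 2 * n].sigmoid()
            g = z[:, 2 * n : 3 * n].tanh()
            o = z[:, 3 * n : 4 * n].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return outputs  # type: ignore[return-value]


class BiLSTM(Module):
    """Bidirectional LSTM over the window axis.

    `return_sequences=True` yields (B, T, 2H); otherwise the concatenated
    final states of both directions, (B, 2H).
    """

    def __init__(
        self,
        in_size: int,
        hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = True,
    ):
        self.forward_cell = _LSTMDirection(in_size, hidden, rng)
        self.backward_cell = _LSTMDirection(in_size, hidden, rng)
        self.return_sequences = return_sequences

    def forward(self, x: Tensor) -> Tensor:
        fwd = self.forward_cell(x, reverse=False)
        bwd = self.backward_cell(x, reverse=True)
        if self.return_sequences:
            steps = [
                concat([f, b], axis=1).reshape(x.shape[0], 1, -1)
                for f, b in zip(fwd, bwd)
            ]
            return concat(steps, axis=1)
        return concat([fwd[-1], bwd[0]], axis=1)


class Dense(Module):
    def __init__(
        self,
        in_size: int,
        out_size: int,
        rng: np.random.Generator,
        activation: str | None = None,
    ):
        self.weight = _glorot(rng, (in_size, out_size), in_size, out_size)
        self.bias = Tensor(np.zeros(out_size), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight + self.bias
        if self.activation == "relu":
            return out.relu()
        if self.activation is None:
            return out
        raise ValueError(f"unknown activation {self.activation!r}")


class Dropout(Module):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Conv2dSame(Module):
    """Square 2D convolution over (B, L, L, C) pair tensors, zero-padded so
    the two spatial dimensions are preserved for any L."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
    ):
        if kernel < 1:
            raise ValueError("kernel must be positive")
        self.kernel = kernel
        self.weight = _glorot(
            rng,
            (kernel, kernel, in_channels, filters),
            kernel * kernel * in_channels,
            filters,
        )
        self.bias = Tensor(np.zeros(filters), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        height, width = x.shape[1], x.shape[2]
        before = (self.kernel - 1) // 2
        after = self.kernel // 2
        xp = x.pad_axis(1, before, after).pad_axis(2, before, after)
        acc = None
        for a in range(self.kernel):
            for b in range(self.kernel):
                term = xp[:, a : a + height, b : b + width, :] @ self.weight[a, b]
                acc = term if acc is None else acc + term
        return acc + self.bias


class BatchNorm(Module):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if train:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return self.gamma * xhat + self.beta
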