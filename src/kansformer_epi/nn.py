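"""Neural-network building blocks (Linear, Conv1d, BiLSTM, attention, ...).

Modules mirror the familiar layer vocabulary but run on the package's own
numpy autodiff tape.  Every module takes an explicit ``numpy.random.Generator``
for parameter initialisation so model construction is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / submodule discovery --------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        self._set_training(True)
        return self

    def eval(self) -> "Module":
        self._set_training(False)
        return self

    def _set_training(self, flag: bool) -> None:
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_training(flag)

    # -- (de)serialisation -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch; missing={sorted(missing)} "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv1dSame(Module):
    """1-D convolution with stride 1 and zero same-padding (odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("same-padding convolution requires an odd kernel")
        self.kernel = kernel
        self.in_channels = in_channels
        scale = 1.0 / np.sqrt(in_channels * kernel)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(in_channels * kernel, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        # x: (batch, in_channels, length) -> (batch, out_channels, length)
        batch, cin, length = x.shape
        if cin != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {cin}")
        p = self.kernel // 2
        xp = ad.pad_last(x, p, p)
        idx = np.arange(length)[:, None] + np.arange(self.kernel)[None, :]
        cols = xp[:, :, idx]                    # (batch, cin, length, kernel)
        cols = cols.transpose(0, 2, 1, 3).reshape(batch, length, cin * self.kernel)
        y = cols @ self.weight + self.bias      # (batch, length, cout)
        return y.transpose(0, 2, 1)


class MaxPool1d(Module):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        batch, channels, length = x.shape
        if length % self.pool:
            raise ValueError(f"length {length} not divisible by pool {self.pool}")
        return x.reshape(batch, channels, length // self.pool, self.pool).max(axis=-1)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.p, self.rng, self.training)


class LSTM(Module):
    """Single-layer unidirectional LSTM over (batch, length, width) input."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        self.w_x = Parameter(rng.uniform(-scale, scale, size=(n_in, 4 * hidden)))
        self.w_h = Parameter(rng.uniform(-scale, scale, size=(hidden, 4 * hidden)))
        self.bias = Parameter(np.zeros(4 * hidden))

    def forward(self, x: Tensor) -> Tensor:
        batch, length, _ = x.shape
        hdim = self.hidden
        h = Tensor(np.zeros((batch, hdim)))
        c = Tensor(np.zeros((batch, hdim)))
        xw = x @ self.w_x + self.bias          # precompute input contributions
        outs = []
        for t in range(length):
            gates = xw[:, t, :] + h @ self.w_h
            i = ad.sigmoid(gates[:, 0:hdim])
            f = ad.sigmoid(gates[:, hdim:2 * hdim])
            g = ad.tanh(gates[:, 2 * hdim:3 * hdim])
            o = ad.sigmoid(gates[:, 3 * hdim:4 * hdim])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h)
        return ad.stack(outs, axis=1)


class BiLSTM(Module):
    """Concatenates forward and time-reversed LSTM passes: width 2*hidden."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(n_in, hidden, rng)
        self.bwd = LSTM(n_in, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        length = x.shape[1]
        rev = np.arange(length)[::-1].copy()
        out_f = self.fwd(x)
        out_b = self.bwd(x[:, rev, :])[:, rev, :]
        return ad.concatenate([out_f, out_b], axis=-1)


class MultiheadAttention(Module):
    """Multi-head self-attention with a learned output projection and bias.

    ``literal_mv`` switches to a variant in which the per-head attention
    output is additionally modulated elementwise by the value encoding before
    the output projection (the shape-consistent reading of applying the
    relationship matrix to V a second time).
    """

    def __init__(self, width: int, heads: int, rng: np.random.Generator,
                 literal_mv: bool = False):
        super().__init__()
        if width % heads:
            raise ValueError(f"width {width} not divisible by heads {heads}")
        self.width = width
        self.heads = heads
        self.literal_mv = literal_mv
        self.w_q = Linear(width, width, rng, bias=False)
        self.w_k = Linear(width, width, rng, bias=False)
        self.w_v = Linear(width, width, rng, bias=False)
        self.w_out = Linear(width, width, rng, bias=True)

    def _split(self, t: Tensor, batch: int, length: int) -> Tensor:
        dk = self.width // self.heads
        return t.reshape(batch, length, self.heads, dk).transpose(0, 2, 1, 3)

    def forward(self, z: Tensor, return_weights: bool = False):
        batch, length, width = z.shape
        dk = width // self.heads
        q = self._split(self.w_q(z), batch, length)
        k = self._split(self.w_k(z), batch, length)
        v = self._split(self.w_v(z), batch, length)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        attn = ad.softmax(scores, axis=-1)      # (batch, heads, length, length)
        m = attn @ v
        if self.literal_mv:
            m = m * v
        merged = m.transpose(0, 2, 1, 3).reshape(batch, length, width)
        out = self.w_out(merged)
        if return_weights:
            return out, attn
        return out
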