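"""The EPI prediction network.

Architecture, applied to a (bins x channels) signal window per pair:

1. 1-D CNN (same padding) + ReLU extracts local signal patterns;
2. max pooling shortens the sequence (5000 -> 500 positions by default);
3. a BiLSTM summarises both directions into a width-h sequence Z;
4. a stack of encoder blocks alternates pre-norm multi-head self-attention
   and a position-wise two-layer KAN (h -> ff_hidden -> h), each with a
   residual connection, giving H0;
5. a self-attention embedding A_s = softmax(W2 tanh(W1 H0^T)) pools H0 into
   r weighted rows H1 = A_s H0;
6. the mean and max over H1's rows are concatenated with the encoder hidden
   states at the enhancer and promoter positions: H = avg || max || h_e || h_p
   (width 4h);
7. two KAN heads map H to the interaction probability p = sigmoid(KAN1(H))
   and the scaled anchor distance d_p = KAN2(H).

Training optimises L = L_class + L_dist, binary cross-entropy plus a mean
squared error on the distance (distance in bp / window size, so both terms
are commensurate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .kan import KANNetwork, SplineBasisSpec
from .nn import (BiLSTM, Conv1dSame, Dropout, LayerNorm, Linear, MaxPool1d,
                 Module, MultiheadAttention)

PROB_CLAMP = 1e-7


@dataclass
class ModelConfig:
    in_channels: int = 8
    bins: int = 5000
    cnn_channels: int = 180
    kernel: int = 11
    pool: int = 10
    hidden: int = 180            # h: BiLSTM output width (h/2 per direction)
    encoder_layers: int = 3
    heads: int = 6
    ff_hidden: int = 256         # KAN block width inside each encoder layer
    attn_pool_s: int = 64
    attn_pool_r: int = 8
    head_dims: tuple[int, int] = (128, 64)
    dropout: float = 0.2             # after each KAN head hidden layer
    encoder_dropout: float = 0.1     # on each residual branch of the encoder
    literal_mv: bool = False
    spline: SplineBasisSpec = field(default_factory=SplineBasisSpec)

    def __post_init__(self):
        if self.hidden % 2:
            raise ValueError("hidden width must be even (two LSTM directions)")
        if self.hidden % self.heads:
            raise ValueError("hidden width must be divisible by heads")
        if self.bins % self.pool:
            raise ValueError("bins must be divisible by the pooling size")
        for name in ("in_channels", "bins", "cnn_channels", "kernel", "pool",
                     "hidden", "encoder_layers", "heads", "ff_hidden",
                     "attn_pool_s", "attn_pool_r"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def small(cls, in_channels: int = 8, bins: int = 500) -> "ModelConfig":
        """Reduced configuration for CPU-scale runs (h=64, one encoder layer).

        Pooling is 5 rather than 10 so a 500-bin window still yields a
        ~100-position sequence, keeping the pooled-resolution-to-window
        proportion of the full-scale configuration (5000 -> 500).
        """
        return cls(in_channels=in_channels, bins=bins, cnn_channels=64,
                   pool=5, hidden=64, encoder_layers=1, heads=4, ff_hidden=64,
                   attn_pool_s=32, attn_pool_r=4, head_dims=(32, 16))

    @property
    def pooled_length(self) -> int:
        return self.bins // self.pool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spline"] = self.spline.to_dict()
        d["head_dims"] = list(self.head_dims)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["spline"] = SplineBasisSpec.from_dict(d["spline"])
        d["head_dims"] = tuple(d["head_dims"])
        return ModelConfig(**d)


@dataclass
class ForwardState:
    """Intermediate activations of one forward pass (for inspection/tests)."""

    Z: np.ndarray          # (batch, l, h) BiLSTM output
    H0: np.ndarray         # (batch, l, h) encoder output
    A_s: np.ndarray        # (batch, r, l) pooling attention, rows sum to 1
    H1: np.ndarray         # (batch, r, h) weighted embedding
    h_e: np.ndarray        # (batch, h) anchor state at the enhancer position
    h_p: np.ndarray        # (batch, h) anchor state at the promoter position
    H: np.ndarray          # (batch, 4h) aggregate
    p: np.ndarray          # (batch,) interaction probability
    d_p: np.ndarray        # (batch,) predicted scaled distance


class KansformerBlock(Module):
    """Pre-norm encoder block: attention and position-wise KAN sub-layers.

    Z <- Z + MHA(LN(Z));  Z <- Z + KAN(LN(Z)), the KAN applied independently
    at every sequence position.
    """

    def __init__(self, width: int, heads: int, ff_hidden: int,
                 rng: np.random.Generator, literal_mv: bool = False,
                 spline: SplineBasisSpec | None = None,
                 dropout: float = 0.0):
        super().__init__()
        self.norm1 = LayerNorm(width)
        self.mha = MultiheadAttention(width, heads, rng, literal_mv=literal_mv)
        self.norm2 = LayerNorm(width)
        self.kan = KANNetwork([width, ff_hidden, width], rng, basis=spline)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = z + self.drop1(self.mha(self.norm1(z)))
        return z + self.drop2(self.kan(self.norm2(z)))


class AttentionPool(Module):
    """r-row attention embedding: A_s = softmax(W2 tanh(W1 H0^T)), H1 = A_s H0."""

    def __init__(self, width: int, s: int, r: int, rng: np.random.Generator):
        super().__init__()
        self.w1 = Linear(width, s, rng, bias=False)
        self.w2 = Linear(s, r, rng, bias=False)

    def forward(self, h0: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.w2(ad.tanh(self.w1(h0)))        # (batch, l, r)
        a_s = ad.softmax(scores.transpose(0, 2, 1), axis=-1)   # (batch, r, l)
        return a_s, a_s @ h0


def aggregate(h1: Tensor, h_e: Tensor, h_p: Tensor) -> Tensor:
    """avg-pool(H1) || max-pool(H1) || h_e || h_p, width 4h."""
    avg = h1.mean(axis=1)
    mx = h1.max(axis=1)
    return ad.concatenate([avg, mx, h_e, h_p], axis=-1)


class KansformerEPI(Module):
    """End-to-end EPI classifier + distance regressor over feature windows."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.conv = Conv1dSame(cfg.in_channels, cfg.cnn_channels, cfg.kernel, rng)
        self.pool = MaxPool1d(cfg.pool)
        self.bilstm = BiLSTM(cfg.cnn_channels, cfg.hidden // 2, rng)
        self.blocks = [KansformerBlock(cfg.hidden, cfg.heads, cfg.ff_hidden,
                                       rng, cfg.literal_mv, cfg.spline,
                                       dropout=cfg.encoder_dropout)
                       for _ in range(cfg.encoder_layers)]
        self.attn_pool = AttentionPool(cfg.hidden, cfg.attn_pool_s,
                                       cfg.attn_pool_r, rng)
        d1, d2 = cfg.head_dims
        self.head_class = KANNetwork([4 * cfg.hidden, d1, d2, 1], rng,
                                     basis=cfg.spline, dropout=cfg.dropout)
        self.head_dist = KANNetwork([4 * cfg.hidden, d1, d2, 1], rng,
                                    basis=cfg.spline, dropout=cfg.dropout)

    # -- stages ---------------------------------------------------------------
    def backbone(self, x: Tensor) -> Tensor:
        """(batch, bins, channels) -> BiLSTM sequence Z (batch, l, hidden)."""
        if x.shape[1] % self.cfg.pool:
            raise ValueError(
                f"input length {x.shape[1]} not divisible by pool {self.cfg.pool}")
        feats = ad.relu(self.conv(x.transpose(0, 2, 1)))
        pooled = self.pool(feats)                       # (batch, cnn, l)
        return self.bilstm(pooled.transpose(0, 2, 1))   # (batch, l, hidden)

    def encode(self, z: Tensor) -> Tensor:
        for block in self.blocks:
            z = block(z)
        return z

    def anchor_states(self, h0: Tensor, e_bin: np.ndarray,
                      p_bin: np.ndarray) -> tuple[Tensor, Tensor]:
        length = h0.shape[1]
        idx_e = np.asarray(e_bin) // self.cfg.pool
        idx_p = np.asarray(p_bin) // self.cfg.pool
        if (idx_e >= length).any() or (idx_p >= length).any():
            raise IndexError("anchor bin index outside the pooled sequence")
        rows = np.arange(h0.shape[0])
        return h0[rows, idx_e], h0[rows, idx_p]

    def heads_forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        p = ad.sigmoid(self.head_class(h)).reshape(h.shape[0])
        d_p = self.head_dist(h).reshape(h.shape[0])
        return p, d_p

    def forward(self, x: Tensor | np.ndarray, e_bin: np.ndarray,
                p_bin: np.ndarray, return_state: bool = False):
        x = x if isinstance(x, Tensor) else Tensor(x)
        z = self.backbone(x)
        h0 = self.encode(z)
        a_s, h1 = self.attn_pool(h0)
        h_e, h_p = self.anchor_states(h0, e_bin, p_bin)
        h = aggregate(h1, h_e, h_p)
        p, d_p = self.heads_forward(h)
        if return_state:
            state = ForwardState(Z=z.data, H0=h0.data, A_s=a_s.data,
                                 H1=h1.data, h_e=h_e.data, h_p=h_p.data,
                                 H=h.data, p=p.data, d_p=d_p.data)
            return p, d_p, state
        return p, d_p

    def predict(self, x: np.ndarray, e_bin: np.ndarray,
                p_bin: np.ndarray, batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode batched inference; returns (p, d_p) numpy arrays."""
        was_training = self.training
        self.eval()
        ps, ds = [], []
        try:
            with ad.no_grad():
                for lo in range(0, x.shape[0], batch_size):
                    hi = lo + batch_size
                    p, d_p = self.forward(Tensor(x[lo:hi]), e_bin[lo:hi],
                                          p_bin[lo:hi])
                    ps.append(p.data)
                    ds.append(d_p.data)
        finally:
            if was_training:
                self.train()
        return np.concatenate(ps), np.concatenate(ds)


def combined_loss(p: Tensor, y: np.ndarray, d_p: Tensor,
                  d_t: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
    """(L_class, L_dist, L): binary cross-entropy + distance MSE, summed."""
    y = np.asarray(y, dtype=np.float64)
    d_t = np.asarray(d_t, dtype=np.float64)
    if p.shape[0] != y.shape[0] or d_p.shape[0] != d_t.shape[0]:
        raise ValueError("batch length mismatch between predictions and targets")
    pc = ad.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    yt = Tensor(y)
    l_class = -(yt * ad.log(pc) + (1.0 - yt) * ad.log(1.0 - pc)).mean()
    diff = d_p - Tensor(d_t)
    l_dist = (diff * diff).mean()
    return l_class, l_dist, l_class + l_dist


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: KansformerEPI,
                    normalizer_dict: dict | None = None,
                    channels: list[str] | None = None,
                    extra: dict | None = None) -> None:
    """Model parameters (.npz) + JSON sidecar (config, normalizer, channels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"config": model.cfg.to_dict(), "normalizer": normalizer_dict,
            "channels": channels, "extra": extra or {}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, seed: int = 0
                    ) -> tuple[KansformerEPI, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(meta["config"])
    model = KansformerEPI(cfg, seed=seed)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        model.load_state_dict({k: f[k] for k in f.files})
    return model, meta
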