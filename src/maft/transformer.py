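"""Per-feature sequence encoder and task heads.

One model is trained per feature stream.  The architecture is the classic
post-norm transformer encoder: sinusoidal positional encoding added to the
(optionally linearly projected) input, then N layers of single- or
multi-head scaled dot-product self-attention and a two-layer feed-forward
block, each wrapped in a residual connection followed by layer
normalization.  The encoded sequence is averaged over the temporal axis,
passed through an *embedding FC block* (ReLU -> dropout -> linear) to a
shared fixed-size embedding, and finally through two independent FC blocks
of the same shape: a regression head emitting one real PHQ-8 score and a
classification head emitting 5 severity-class logits.

Everything runs on the :mod:`maft.autodiff` tape so a single training
step is one forward pass, one ``backward()`` and an Adam update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

N_SEVERITY_CLASSES = 5


class NumericError(FloatingPointError):
    """NaN/Inf detected in activations, annotated with the layer."""


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    ``d_model=None`` means "use the input feature dimension directly"
    (no input projection), which is the default operating mode; setting it
    adds a learned linear projection before the positional encoding.
    """

    num_layers: int = 6
    num_heads: int = 1
    ff_hidden: int = 2048
    d_model: int | None = None
    embed_dim: int = 256
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.num_layers < 0 or self.num_heads < 1:
            raise ValueError("num_layers must be >= 0 and num_heads >= 1")
        if self.ff_hidden < 1 or self.embed_dim < 1:
            raise ValueError("dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def resolve_d_model(self, input_dim: int) -> int:
        d_model = self.d_model if self.d_model is not None else input_dim
        if d_model % self.num_heads != 0:
            raise ValueError(
                f"d_model={d_model} not divisible by num_heads={self.num_heads}"
            )
        return d_model


def positional_encoding(t: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding matrix of shape (t, d_model).

    Column pair (2i, 2i+1) holds sin and cos of pos / 10000^(2i/d_model).
    For odd d_model the final unpaired column takes the sine term.
    """
    if t < 1 or d_model < 1:
        raise ValueError("t and d_model must be positive")
    pos = np.arange(t)[:, None]
    i = np.arange(0, d_model, 2)[None, :]
    angles = pos / (10000.0 ** (i / d_model))
    pe = np.zeros((t, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)[:, : d_model // 2]
    return pe


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    k = 1.0 / np.sqrt(fan_in)
    w = Tensor(rng.uniform(-k, k, size=(fan_in, fan_out)), requires_grad=True)
    b = Tensor(rng.uniform(-k, k, size=(fan_out,)), requires_grad=True)
    return w, b


class Linear:
    def __init__(self, rng, fan_in: int, fan_out: int):
        self.w, self.b = _init_linear(rng, fan_in, fan_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (eval mode)."""
    if rng is None or rate == 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


@dataclass
class AttentionWeights:
    """Learned Q/K/V and output projections of one attention block."""

    wq: Linear
    wk: Linear
    wv: Linear
    wo: Linear
    num_heads: int = 1

    @classmethod
    def create(cls, rng, d_model: int, num_heads: int) -> "AttentionWeights":
        return cls(
            wq=Linear(rng, d_model, d_model),
            wk=Linear(rng, d_model, d_model),
            wv=Linear(rng, d_model, d_model),
            wo=Linear(rng, d_model, d_model),
            num_heads=num_heads,
        )

    def params(self) -> list[Tensor]:
        return [p for lin in (self.wq, self.wk, self.wv, self.wo) for p in lin.params()]


def self_attention(x: Tensor, weights: AttentionWeights) -> Tensor:
    """Scaled dot-product self-attention, heads concatenated and projected.

    ``x`` is (batch, t, d_model).  Per head: Z = softmax(Q K^T / sqrt(d_k)) V
    with the similarity matrix row-normalized (each query's attention over
    keys sums to 1).
    """
    b, t, d_model = x.shape
    h = weights.num_heads
    d_k = d_model // h
    q = weights.wq(x)
    k = weights.wk(x)
    v = weights.wv(x)

    def split_heads(m: Tensor) -> Tensor:
        # (b, t, d_model) -> (b, h, t, d_k)
        return m.reshape(b, t, h, d_k).transpose(0, 2, 1, 3)

    q, k, v = split_heads(q), split_heads(k), split_heads(v)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d_k))
    attn = scores.softmax(axis=-1)
    z = attn @ v  # (b, h, t, d_k)
    z = z.transpose(0, 2, 1, 3).reshape(b, t, d_model)
    return weights.wo(z)


def attention_matrix(x: Tensor, weights: AttentionWeights) -> np.ndarray:
    """The row-stochastic attention weights, shape (b, h, t, t)."""
    b, t, d_model = x.shape
    h = weights.num_heads
    d_k = d_model // h
    q = weights.wq(x).reshape(b, t, h, d_k).transpose(0, 2, 1, 3)
    k = weights.wk(x).reshape(b, t, h, d_k).transpose(0, 2, 1, 3)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1).data


class EncoderLayer:
    """Post-norm block: LN(x + attention(x)), then LN(x + feed-forward(x))."""

    def __init__(self, rng, d_model: int, num_heads: int, ff_hidden: int,
                 dropout: float):
        self.attn = AttentionWeights.create(rng, d_model, num_heads)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, ff_hidden)
        self.ff2 = Linear(rng, ff_hidden, d_model)
        self.norm2 = LayerNorm(d_model)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        a = _dropout(self_attention(x, self.attn), self.dropout, rng)
        x = self.norm1(x + a)
        f = _dropout(self.ff2(self.ff1(x).relu()), self.dropout, rng)
        return self.norm2(x + f)

    def params(self) -> list[Tensor]:
        return (self.attn.params() + self.norm1.params() + self.ff1.params()
                + self.ff2.params() + self.norm2.params())


class FCBlock:
    """ReLU -> dropout -> linear, the shared shape of embedding and task heads."""

    def __init__(self, rng, fan_in: int, fan_out: int, dropout: float):
        self.linear = Linear(rng, fan_in, fan_out)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        return self.linear(_dropout(x.relu(), self.dropout, rng))

    def params(self) -> list[Tensor]:
        return self.linear.params()


def temporal_average(h: Tensor) -> Tensor:
    """Mean over the frame axis: (b, t, d) -> (b, d)."""
    return h.mean(axis=1)


class DepressionTransformer:
    """Full per-feature model: encoder, embedding block and two task heads."""

    CHECKPOINT_VERSION = 1

    def __init__(self, input_dim: int, cfg: EncoderConfig, seed: int = 0):
        self.input_dim = int(input_dim)
        self.cfg = cfg
        self.seed = int(seed)
        self.d_model = cfg.resolve_d_model(input_dim)
        rng = np.random.default_rng(seed)
        self.input_proj = (
            Linear(rng, input_dim, self.d_model)
            if self.d_model != input_dim or cfg.d_model is not None
            else None
        )
        self.layers = [
            EncoderLayer(rng, self.d_model, cfg.num_heads, cfg.ff_hidden, cfg.dropout)
            for _ in range(cfg.num_layers)
        ]
        self.embed_block = FCBlock(rng, self.d_model, cfg.embed_dim, cfg.dropout)
        self.reg_head = FCBlock(rng, cfg.embed_dim, 1, cfg.dropout)
        self.cls_head = FCBlock(rng, cfg.embed_dim, N_SEVERITY_CLASSES, cfg.dropout)
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward pieces ------------------------------------------------------

    def encoder_forward(self, x: np.ndarray | Tensor, train: bool = False,
                        positional: bool = True) -> Tensor:
        """(b, t, d) -> (b, t, d_model) through positional encoding + layers.

        ``positional=False`` skips the positional encoding, leaving the pure
        (permutation-equivariant) attention stack — useful for analysis.
        """
        x = x if isinstance(x, Tensor) else Tensor(x)
        rng = self._dropout_rng if train else None
        if self.input_proj is not None:
            x = self.input_proj(x)
        if positional:
            pe = positional_encoding(x.shape[1], self.d_model)
            x = x + Tensor(pe)
        for idx, layer in enumerate(self.layers):
            x = layer(x, rng)
            if not np.isfinite(x.data).all():
                raise NumericError(f"non-finite activations after encoder layer {idx}")
        return x

    def embed(self, x: np.ndarray | Tensor, train: bool = False) -> Tensor:
        rng = self._dropout_rng if train else None
        h = self.encoder_forward(x, train=train)
        return self.embed_block(temporal_average(h), rng)

    def forward(self, x: np.ndarray | Tensor, train: bool = False
                ) -> tuple[Tensor, Tensor]:
        """Return (scores (b,), class_logits (b, 5))."""
        rng = self._dropout_rng if train else None
        e = self.embed(x, train=train)
        scores = self.reg_head(e, rng).reshape(-1)
        logits = self.cls_head(e, rng)
        return scores, logits

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode predictions: (scores, class probabilities)."""
        scores, logits = self.forward(x, train=False)
        return scores.data.copy(), logits.softmax(axis=-1).data.copy()

    # -- parameters and checkpoints ------------------------------------------

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.input_proj is not None:
            out += self.input_proj.params()
        for layer in self.layers:
            out += layer.params()
        out += self.embed_block.params()
        out += self.reg_head.params()
        out += self.cls_head.params()
        return out

    def state_dict(self) -> dict:
        return {
            "version": self.CHECKPOINT_VERSION,
            "input_dim": self.input_dim,
            "seed": self.seed,
            "config": {
                "num_layers": self.cfg.num_layers,
                "num_heads": self.cfg.num_heads,
                "ff_hidden": self.cfg.ff_hidden,
                "d_model": self.cfg.d_model,
                "embed_dim": self.cfg.embed_dim,
                "dropout": self.cfg.dropout,
            },
            "params": [p.data.copy() for p in self.params()],
        }

    def load_state_dict(self, state: dict) -> None:
        if state.get("version") != self.CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {state.get('version')}")
        params = self.params()
        if len(state["params"]) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, arr in zip(params, state["params"]):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint shape mismatch: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    @classmethod
    def from_state_dict(cls, state: dict) -> "DepressionTransformer":
        cfg = EncoderConfig(**state["config"])
        model = cls(state["input_dim"], cfg, seed=state["seed"])
        model.load_state_dict(state)
        return model
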