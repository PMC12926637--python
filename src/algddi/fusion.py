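"""Multi-scale feature fusion.

Each drug carries three width-d vectors — attribute (a), local (l) and
global (g).  The default strategy stacks them as three tokens and runs a
pre-norm transformer encoder block (multi-head self-attention + position-
wise feed-forward, residual connections around both), then flattens the
tokens and linearly projects back to width d.  No positional encoding is
used: scale identity is carried by the learned projections, so the token
stream is permutation-equivariant.

Baseline strategies: concatenation (3d -> d linear), Hadamard product and
average (d -> d linear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax

STRATEGIES = ("transformer", "concat", "hadamard", "average")


@dataclass
class ScaleEmbeddings:
    """Per-drug (a, l, g) triple plus the fused vector once computed."""

    a: np.ndarray
    l: np.ndarray
    g: np.ndarray
    x: np.ndarray | None = None

    def __post_init__(self):
        if not (len(self.a) == len(self.l) == len(self.g)):
            raise ValueError("scale embeddings must share width d")


@dataclass
class FusionParams:
    d: int
    n_heads: int
    d_k: int
    eps: float
    strategy: str
    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    ff_w1: Tensor
    ff_b1: Tensor
    ff_w2: Tensor
    ff_b2: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    out_w: Tensor
    out_b: Tensor
    n_blocks: int = 1

    def trainables(self):
        return [self.wq, self.wk, self.wv, self.wo, self.ff_w1, self.ff_b1,
                self.ff_w2, self.ff_b2, self.ln1_g, self.ln1_b, self.ln2_g,
                self.ln2_b, self.out_w, self.out_b]


def init_fusion_params(d: int = 128, n_heads: int = 4, strategy: str = "transformer",
                       n_tokens: int = 3, n_blocks: int = 1, eps: float = 1e-5,
                       seed: int = 0) -> FusionParams:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    if d % n_heads:
        raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
    d_k = d // n_heads
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(d)

    def mat(r, c, scale=None):
        return Tensor(rng.normal(0, scale or 1.0 / np.sqrt(r), (r, c)),
                      requires_grad=True)

    in_width = n_tokens * d if strategy in ("transformer", "concat") else d
    return FusionParams(
        d=d, n_heads=n_heads, d_k=d_k, eps=eps, strategy=strategy,
        wq=mat(d, n_heads * d_k, s), wk=mat(d, n_heads * d_k, s),
        wv=mat(d, n_heads * d_k, s), wo=mat(n_heads * d_k, d),
        ff_w1=mat(d, 4 * d), ff_b1=Tensor(np.zeros(4 * d), requires_grad=True),
        ff_w2=mat(4 * d, d), ff_b2=Tensor(np.zeros(d), requires_grad=True),
        ln1_g=Tensor(np.ones(d), requires_grad=True),
        ln1_b=Tensor(np.zeros(d), requires_grad=True),
        ln2_g=Tensor(np.ones(d), requires_grad=True),
        ln2_b=Tensor(np.zeros(d), requires_grad=True),
        out_w=mat(in_width, d),
        out_b=Tensor(np.zeros(d), requires_grad=True),
        n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# autodiff forward (batched: X is (B, T, d))
# ---------------------------------------------------------------------------

def _layer_norm_t(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2.0).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta


def _mha_t(x: Tensor, p: FusionParams, return_weights: bool = False):
    B, T, d = x.shape
    m, dk = p.n_heads, p.d_k

    def split(z):  # (B, T, m*dk) -> (B, m, T, dk)
        return z.reshape(B, T, m, dk).transpose((0, 2, 1, 3))

    q = split(x @ p.wq)
    k = split(x @ p.wk)
    v = split(x @ p.wv)
    scores = q.bmm(k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
    att = softmax(scores, axis=-1)
    out = att.bmm(v)                                   # (B, m, T, dk)
    out = out.transpose((0, 2, 1, 3)).reshape(B, T, m * dk) @ p.wo
    if return_weights:
        return out, att
    return out


def _ffn_t(x: Tensor, p: FusionParams) -> Tensor:
    return (x @ p.ff_w1 + p.ff_b1).relu() @ p.ff_w2 + p.ff_b2


def _block_t(x: Tensor, p: FusionParams) -> Tensor:
    y = x + _mha_t(_layer_norm_t(x, p.ln1_g, p.ln1_b, p.eps), p)
    return y + _ffn_t(_layer_norm_t(y, p.ln2_g, p.ln2_b, p.eps), p)


def fuse_tensor(scale_mats: list, params: FusionParams) -> Tensor:
    """Fuse per-scale (B, d) matrices into fused (B, d) drug vectors."""
    mats = [m if isinstance(m, Tensor) else Tensor(m) for m in scale_mats]
    B, d = mats[0].shape
    T = len(mats)
    if params.strategy == "transformer":
        x = concat([m.reshape(B, 1, d) for m in mats], axis=1)
        for _ in range(params.n_blocks):
            x = _block_t(x, params)
        return x.reshape(B, T * d) @ params.out_w + params.out_b
    if params.strategy == "concat":
        return concat(mats, axis=1) @ params.out_w + params.out_b
    if params.strategy == "hadamard":
        prod = mats[0]
        for m in mats[1:]:
            prod = prod * m
        return prod @ params.out_w + params.out_b
    if params.strategy == "average":
        s = mats[0]
        for m in mats[1:]:
            s = s + m
        return s * (1.0 / T) @ params.out_w + params.out_b
    raise ValueError(f"unknown fusion strategy {params.strategy!r}")


# ---------------------------------------------------------------------------
# plain-array public API
# ---------------------------------------------------------------------------

def layer_norm(x, gamma, beta, eps: float = 1e-5) -> np.ndarray:
    """(x - mean) / sqrt(var + eps) * gamma + beta over the last axis."""
    return _layer_norm_t(Tensor(x), Tensor(gamma), Tensor(beta), eps).data


def multi_head_attention(tokens, params: FusionParams, return_weights: bool = False):
    """Self-attention over a (T, d) token matrix; optionally the (m, T, T)
    attention weights (each row sums to 1)."""
    x = Tensor(np.asarray(tokens, dtype=np.float64)[None])
    if return_weights:
        out, att = _mha_t(x, params, return_weights=True)
        return out.data[0], att.data[0]
    return _mha_t(x, params).data[0]


def transformer_encoder_block(tokens, params: FusionParams) -> np.ndarray:
    """Pre-norm encoder block on a (T, d) token matrix."""
    out = _block_t(Tensor(np.asarray(tokens, dtype=np.float64)[None]), params)
    return out.data[0]


def fuse(scales: ScaleEmbeddings, strategy: str, params: FusionParams) -> np.ndarray:
    """Fuse one drug's (a, l, g) into x (width d) under ``strategy``."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    if strategy != params.strategy:
        raise ValueError(
            f"params were initialized for {params.strategy!r}, not {strategy!r}"
        )
    out = fuse_tensor(
        [scales.a[None], scales.l[None], scales.g[None]], params
    ).data[0]
    scales.x = out
    return out
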