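"""The Translution Block: Fire pre-processing, patch tokenization,
transformer encoding and channel-doubling fusion.

Stage 2 of the network takes a C=128, H×W feature map and

1. expands it with a Fire module 128 → 256 and reduces with a second
   Fire module 256 → 64 (local representation learning),
2. rearranges the 64-channel map into tokens: with patches of size h×w
   there are P = h·w pixel positions and N = (H·W)/(h·w) patches; each of
   the P positions yields a sequence of N tokens of dimension 64, so the
   local pixel order is preserved and no positional embeddings are needed,
3. runs a small pre-norm transformer encoder over the N axis with scaled
   dot-product attention  Attention(Q,K,V) = softmax(QKᵀ/√d_k)·V,
4. folds the tokens back to a 64-channel map, projects it with a 1×1 conv
   to C channels and concatenates it with the block input (C_output = 2C),
5. reduces 2C → C with a final Fire module.

The block is (C, H, W)-preserving.  If H or W is not divisible by the
patch side the map is zero-padded bottom/right before unfolding and
cropped after folding; the default 224-pixel pipeline (28×28 map, 4×4
patches) needs no padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigurationError, GridError, ShapeError
from .fire import FireModule, derive_fire_channels

__all__ = [
    "PatchGrid",
    "AttentionSpec",
    "TranslutionConfig",
    "unfold_patches",
    "fold_patches",
    "attention",
    "TransformerEncoder",
    "TranslutionBlock",
]


@dataclass(frozen=True)
class PatchGrid:
    """An h×w patch tiling of an H×W feature map."""

    H: int
    W: int
    h: int
    w: int

    def __post_init__(self):
        if min(self.H, self.W, self.h, self.w) < 1:
            raise GridError("grid dims must be positive")
        if self.h > self.H or self.w > self.W:
            raise GridError(
                f"patch {self.h}x{self.w} larger than map {self.H}x{self.W}"
            )

    @property
    def padded_hw(self) -> tuple[int, int]:
        """Map dims after bottom/right zero padding to patch multiples."""
        Hp = math.ceil(self.H / self.h) * self.h
        Wp = math.ceil(self.W / self.w) * self.w
        return Hp, Wp

    @property
    def pixels_per_patch(self) -> int:
        """P = h·w."""
        return self.h * self.w

    @property
    def n_patches(self) -> int:
        """N = (H·W)/(h·w), on the padded map."""
        Hp, Wp = self.padded_hw
        return (Hp * Wp) // (self.h * self.w)


@dataclass(frozen=True)
class AttentionSpec:
    """Encoder hyperparameters for the token sequences."""

    token_dim: int = 64
    d_k: int = 16          # per-head query/key width
    d_v: int = 16          # per-head value width
    heads: int = 4
    depth: int = 2
    ffn_width: int = 128
    dropout: float = 0.0   # exposed; the default pipeline uses none

    def __post_init__(self):
        if self.d_k < 1:
            raise ConfigurationError("d_k must be positive")
        if self.d_k * self.heads != self.token_dim or self.d_v * self.heads != self.token_dim:
            raise ConfigurationError(
                f"heads*d_k and heads*d_v must equal token_dim={self.token_dim}"
            )
        if self.depth < 1 or self.ffn_width < 1:
            raise ConfigurationError("depth and ffn_width must be positive")


@dataclass(frozen=True)
class TranslutionConfig:
    """Full Stage-2 layout around C input/output channels."""

    c: int = 128
    inner_dim: int = 64    # token width after the reducing Fire module
    expand_dim: int = 256  # width after the expanding Fire module
    patch_h: int = 4
    patch_w: int = 4
    attention: AttentionSpec = field(default_factory=AttentionSpec)

    def __post_init__(self):
        if self.attention.token_dim != self.inner_dim:
            raise ConfigurationError(
                f"attention token_dim {self.attention.token_dim} must equal "
                f"inner_dim {self.inner_dim}"
            )

    @property
    def c_output_concat(self) -> int:
        """Width of the fusion concat: C_output = 2C."""
        return 2 * self.c


# ---------------------------------------------------------------------------
# patch (un)folding
# ---------------------------------------------------------------------------

def unfold_patches(x: nn.Tensor | np.ndarray, grid: PatchGrid) -> nn.Tensor:
    """(B,C,H,W) → (B, P, N, C) token array.

    Token (p, n) is the channel vector of intra-patch pixel position p in
    patch n; the rearrangement is a bijection (N·P = H·W on the padded
    map), so local pixel order is fully recoverable.
    """
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x))
    B, C, H, W = x.shape
    if (H, W) != (grid.H, grid.W):
        raise GridError(f"grid built for {grid.H}x{grid.W}, map is {H}x{W}")
    Hp, Wp = grid.padded_hw
    x = nn.pad2d_br(x, Hp - H, Wp - W)
    nh, nw = Hp // grid.h, Wp // grid.w
    t = nn.reshape(x, (B, C, nh, grid.h, nw, grid.w))
    t = nn.transpose(t, (0, 3, 5, 2, 4, 1))        # (B, h, w, nh, nw, C)
    return nn.reshape(t, (B, grid.pixels_per_patch, grid.n_patches, C))


def fold_patches(tokens: nn.Tensor | np.ndarray, grid: PatchGrid) -> nn.Tensor:
    """Exact inverse of :func:`unfold_patches`: (B,P,N,C) → (B,C,H,W)."""
    if not isinstance(tokens, nn.Tensor):
        tokens = nn.Tensor(np.asarray(tokens))
    B, P, N, C = tokens.shape
    if P != grid.pixels_per_patch or N != grid.n_patches:
        raise ShapeError(
            f"token array ({P} positions, {N} patches) inconsistent with grid "
            f"(P={grid.pixels_per_patch}, N={grid.n_patches})"
        )
    Hp, Wp = grid.padded_hw
    nh, nw = Hp // grid.h, Wp // grid.w
    t = nn.reshape(tokens, (B, grid.h, grid.w, nh, nw, C))
    t = nn.transpose(t, (0, 5, 3, 1, 4, 2))        # (B, C, nh, h, nw, w)
    t = nn.reshape(t, (B, C, Hp, Wp))
    return nn.crop2d(t, grid.H, grid.W)


# ---------------------------------------------------------------------------
# attention and encoder
# ---------------------------------------------------------------------------

def attention(q: nn.Tensor | np.ndarray, k: nn.Tensor | np.ndarray,
              v: nn.Tensor | np.ndarray) -> nn.Tensor:
    """Scaled dot-product attention softmax(QKᵀ/√d_k)·V.

    Works on (..., N, d) stacks; each output row is a convex combination
    of V's rows.
    """
    q = q if isinstance(q, nn.Tensor) else nn.Tensor(np.asarray(q))
    k = k if isinstance(k, nn.Tensor) else nn.Tensor(np.asarray(k))
    v = v if isinstance(v, nn.Tensor) else nn.Tensor(np.asarray(v))
    d_k = q.shape[-1]
    if d_k == 0:
        raise ConfigurationError("d_k must be positive")
    if k.shape[-1] != d_k:
        raise ShapeError(f"Q has d_k={d_k} but K has {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ShapeError("K and V must agree on the token axis")
    kt = nn.transpose(k, tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2))
    scores = nn.matmul(q, kt) * (1.0 / math.sqrt(d_k))
    return nn.matmul(nn.softmax(scores), v)


class _EncoderLayer(nn.Module):
    """Pre-norm multi-head attention + feed-forward with residuals."""

    def __init__(self, spec: AttentionSpec, rng: np.random.Generator):
        d = spec.token_dim
        self.spec = spec
        self.ln1_g, self.ln1_b = nn.ones_param(d), nn.zeros_param(d)
        self.w_q = nn.kaiming_linear(rng, d, spec.heads * spec.d_k)
        self.b_q = nn.zeros_param(spec.heads * spec.d_k)
        self.w_k = nn.kaiming_linear(rng, d, spec.heads * spec.d_k)
        self.b_k = nn.zeros_param(spec.heads * spec.d_k)
        self.w_v = nn.kaiming_linear(rng, d, spec.heads * spec.d_v)
        self.b_v = nn.zeros_param(spec.heads * spec.d_v)
        self.w_o = nn.kaiming_linear(rng, spec.heads * spec.d_v, d)
        self.b_o = nn.zeros_param(d)
        self.ln2_g, self.ln2_b = nn.ones_param(d), nn.zeros_param(d)
        self.w_f1 = nn.kaiming_linear(rng, d, spec.ffn_width)
        self.b_f1 = nn.zeros_param(spec.ffn_width)
        self.w_f2 = nn.kaiming_linear(rng, spec.ffn_width, d)
        self.b_f2 = nn.zeros_param(d)

    def _split_heads(self, t: nn.Tensor, width: int) -> nn.Tensor:
        B, P, N, _ = t.shape
        t = nn.reshape(t, (B, P, N, self.spec.heads, width))
        return nn.transpose(t, (0, 1, 3, 2, 4))    # (B, P, heads, N, width)

    def __call__(self, t: nn.Tensor) -> nn.Tensor:
        spec = self.spec
        B, P, N, d = t.shape
        h = nn.layer_norm(t, self.ln1_g, self.ln1_b)
        q = self._split_heads(nn.add(nn.matmul(h, self.w_q), self.b_q), spec.d_k)
        k = self._split_heads(nn.add(nn.matmul(h, self.w_k), self.b_k), spec.d_k)
        v = self._split_heads(nn.add(nn.matmul(h, self.w_v), self.b_v), spec.d_v)
        a = attention(q, k, v)                      # (B, P, heads, N, d_v)
        a = nn.transpose(a, (0, 1, 3, 2, 4))
        a = nn.reshape(a, (B, P, N, spec.heads * spec.d_v))
        a = nn.add(nn.matmul(a, self.w_o), self.b_o)
        t = nn.add(t, a)
        h = nn.layer_norm(t, self.ln2_g, self.ln2_b)
        f = nn.relu(nn.add(nn.matmul(h, self.w_f1), self.b_f1))
        f = nn.add(nn.matmul(f, self.w_f2), self.b_f2)
        return nn.add(t, f)


class TransformerEncoder(nn.Module):
    """A stack of pre-norm encoder layers.

    No positional embeddings are added: the patch rearrangement keeps the
    local pixel order, so token identity is positional by construction.
    Purely residual form — with the attention output projection and the
    second FFN weights zeroed, the encoder is the identity map.
    """

    def __init__(self, spec: AttentionSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers = [_EncoderLayer(spec, rng) for _ in range(spec.depth)]

    def __call__(self, tokens: nn.Tensor | np.ndarray) -> nn.Tensor:
        if not isinstance(tokens, nn.Tensor):
            tokens = nn.Tensor(np.asarray(tokens, dtype=np.float32))
        if tokens.shape[-1] != self.spec.token_dim:
            raise ShapeError(
                f"tokens have dim {tokens.shape[-1]}, encoder expects "
                f"{self.spec.token_dim}"
            )
        for layer in self.layers:
            tokens = layer(tokens)
        return tokens


# ---------------------------------------------------------------------------
# the block
# ---------------------------------------------------------------------------

class TranslutionBlock(nn.Module):
    """Stage 2: (C, H, W)-preserving global-context block."""

    def __init__(self, cfg: TranslutionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.fire_expand = FireModule(
            derive_fire_channels(cfg.c, cfg.expand_dim), rng)
        self.fire_reduce = FireModule(
            derive_fire_channels(cfg.expand_dim, cfg.inner_dim), rng)
        self.encoder = TransformerEncoder(cfg.attention, rng)
        self.w_proj = nn.kaiming_conv(rng, cfg.c, cfg.inner_dim, 1)
        self.b_proj = nn.zeros_param(cfg.c)
        self.fire_fuse = FireModule(
            derive_fire_channels(cfg.c_output_concat, cfg.c), rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.c:
            raise ShapeError(
                f"Translution Block expects {cfg.c} channels, got {x.shape[1]}"
            )
        B, C, H, W = x.shape
        local = self.fire_reduce(self.fire_expand(x))
        grid = PatchGrid(H, W, cfg.patch_h, cfg.patch_w)
        tokens = unfold_patches(local, grid)
        tokens = self.encoder(tokens)
        glob = fold_patches(tokens, grid)
        glob = nn.conv2d(glob, self.w_proj, self.b_proj)   # 1×1, inner → C
        fused = nn.concat([x, glob], axis=1)               # C_output = 2C
        return self.fire_fuse(fused)


def translution_forward(x: nn.Tensor | np.ndarray,
                        block: TranslutionBlock) -> nn.Tensor:
    """Functional forward through a Translution Block."""
    if not isinstance(x, nn.Tensor):
        x = nn.Tensor(np.asarray(x, dtype=np.float32))
    return block(x)
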