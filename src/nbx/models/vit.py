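"""Vision transformer branch with token-wise conceptual attention pooling.

The image is cut into non-overlapping P x P patches, flattened and linearly
projected to D dimensions; a learnable class token is prepended and a
learnable positional encoding added:

    T_0 = [t_cls || X_p] + P_pos,      N = H*W / P^2 tokens.

L pre-norm encoder blocks refine the sequence to T_L.  Pooling is not the
class token but a *conceptual attention* over all N+1 tokens:

    alpha_i = softmax_i( v . relu(W T_L,i) ),   f_vit = sum_i alpha_i T_L,i

so f_vit is a convex combination of tokens and alpha is a simplex row
exposing which patches carried the decisive concepts.

Profiles: ``paper`` (P=16, D=768, L=6, 8 heads) matches the printed 768-d
f_vit contract; ``tiny`` (P=8, D=64, L=2, 4 heads) keeps tests CPU-cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._tensor import Tensor, concat
from ..nn import (ParamDict, encoder_block, init_encoder_block, param)


@dataclass
class VitConfig:
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 2
    heads: int = 4
    mlp_ratio: float = 2.0
    use_positions: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")

    @classmethod
    def paper(cls) -> "VitConfig":
        return cls(patch_size=16, embed_dim=768, depth=6, heads=8, mlp_ratio=4.0)

    @classmethod
    def tiny(cls) -> "VitConfig":
        return cls()

    def num_patches(self, side: int) -> int:
        if side % self.patch_size:
            raise ValueError(
                f"image side {side} not divisible by patch size {self.patch_size}")
        return (side // self.patch_size) ** 2


def init_vit(cfg: VitConfig, rng: np.random.Generator, side: int,
             in_channels: int = 3) -> ParamDict:
    n = cfg.num_patches(side)
    d = cfg.embed_dim
    p: ParamDict = {}
    patch_dim = in_channels * cfg.patch_size ** 2
    p["vit.proj.w"] = param(rng, (d, patch_dim), 1.0 / np.sqrt(patch_dim))
    p["vit.proj.b"] = param(rng, (d,), "zeros")
    p["vit.cls"] = param(rng, (1, 1, d), 0.02)
    p["vit.pos"] = param(rng, (1, n + 1, d), 0.02)
    for l in range(cfg.depth):
        init_encoder_block(rng, p, f"vit.block{l}", d, cfg.mlp_ratio)
    p["concept.w"] = param(rng, (d, d), 1.0 / np.sqrt(d))
    p["concept.v"] = param(rng, (d,), 1.0 / np.sqrt(d))
    return p


def patch_embed(images: Tensor | np.ndarray, cfg: VitConfig, params: ParamDict
                ) -> Tensor:
    """Patchify, project, prepend the class token and add positions."""
    x = images if isinstance(images, Tensor) else Tensor(images)
    b, c, h, w = x.shape
    ps = cfg.patch_size
    n_side = h // ps
    if h % ps or w % ps:
        raise ValueError(f"image side {h}x{w} not divisible by patch size {ps}")
    # (B,C,H,W) -> (B, N, C*ps*ps) in row-major patch order
    x = x.reshape(b, c, n_side, ps, n_side, ps)
    x = x.transpose(0, 2, 4, 1, 3, 5).reshape(b, n_side * n_side, c * ps * ps)
    tokens = x @ params["vit.proj.w"].transpose(1, 0) + params["vit.proj.b"]
    cls = params["vit.cls"] * Tensor(np.ones((b, 1, 1)))
    seq = concat([cls, tokens], axis=1)
    if cfg.use_positions:
        seq = seq + params["vit.pos"]
    return seq


def transformer_stack(t0: Tensor, cfg: VitConfig, params: ParamDict) -> Tensor:
    """Apply the L pre-norm encoder blocks in order (L=0 is the identity)."""
    x = t0
    for l in range(cfg.depth):
        x = encoder_block(x, params, f"vit.block{l}", cfg.heads, cfg.mlp_ratio)
    return x


def conceptual_attention(tl: Tensor, params: ParamDict
                         ) -> tuple[Tensor, Tensor]:
    """Softmax-pool the token sequence into f_vit.

    Returns ``(f_vit, alpha)`` with alpha of shape (B, N+1) on the simplex.
    """
    scores = (tl @ params["concept.w"].transpose(1, 0)).relu() @ params["concept.v"]
    alpha = scores.softmax(axis=-1)                        # B x (N+1)
    b, t, d = tl.shape
    f_vit = (tl * alpha.reshape(b, t, 1)).sum(axis=1)      # B x D
    return f_vit, alpha
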