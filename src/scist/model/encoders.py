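"""The two SciSt encoders.

The expression encoder lifts the N_G-dimensional IE prior to a single
d_att-wide token: Linear -> GELU -> Linear.  The image encoder runs the CNN
trunk, flattens the final feature grid to N_coord tokens, and refines them
with one channel self-attention (CSA) block followed by one spatial
self-attention (SSA) block, each with a residual connection and layer norm.
CSA attends over the channel axis (the N_coord positions act as features),
SSA over the spatial positions.
"""

from __future__ import annotations

import numpy as np

from ..nn import Module, Linear, LayerNorm, MultiheadAttention, Tensor
from .config import ModelConfig
from .resnet import ResNet34Trunk, SmallConvTrunk

#: Standard image-classification channel statistics used to normalise patches.
IMAGE_MEAN = np.array([0.485, 0.456, 0.406])
IMAGE_STD = np.array([0.229, 0.224, 0.225])


def normalize_patches(images: np.ndarray) -> np.ndarray:
    """uint8 RGB [B,H,W,3] (or a single patch) -> standardised [B,3,H,W]."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    x = images.astype(np.float64) / 255.0
    x = (x - IMAGE_MEAN) / IMAGE_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class ExprEncoder(Module):
    """IE vector [B, N_G] -> expression token [B, 1, d_att]."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.fc1 = Linear(cfg.n_genes, cfg.expr_hidden, rng)
        self.fc2 = Linear(cfg.expr_hidden, cfg.d_att, rng)
        self.n_genes = cfg.n_genes

    def __call__(self, ie: Tensor) -> Tensor:
        if ie.shape[-1] != self.n_genes:
            raise ValueError(f"IE length {ie.shape[-1]} != n_genes "
                             f"{self.n_genes}")
        out = self.fc2(self.fc1(ie).gelu())
        B = out.shape[0]
        return out.reshape(B, 1, out.shape[-1])


class ImageEncoder(Module):
    """Patch [B,3,H,W] -> image tokens [B, N_coord, d_att]."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        if cfg.backbone == "resnet34":
            self.trunk = ResNet34Trunk(rng)
        elif cfg.backbone == "small":
            self.trunk = SmallConvTrunk(cfg.d_att, cfg.small_channels, rng)
        else:
            raise ValueError(f"unknown backbone {cfg.backbone!r}")
        if self.trunk.out_channels != cfg.d_att:
            raise ValueError(f"backbone channels {self.trunk.out_channels} "
                             f"!= d_att {cfg.d_att}")
        self.use_attention = cfg.variant != "plain_resnet34"
        if self.use_attention:
            self.csa = MultiheadAttention(cfg.n_coord, cfg.csa_heads, rng)
            self.csa_norm = LayerNorm(cfg.d_att)
            self.ssa = MultiheadAttention(cfg.d_att, cfg.n_heads, rng)
            self.ssa_norm = LayerNorm(cfg.d_att)
        self.n_coord = cfg.n_coord

    def __call__(self, x: Tensor, record: dict | None = None) -> Tensor:
        fmap = self.trunk(x)  # [B, C, h, w]
        B, C, h, w = fmap.shape
        if h * w != self.n_coord:
            raise ValueError(f"feature grid {h}x{w} gives {h * w} tokens, "
                             f"config expects {self.n_coord}")
        tokens = fmap.reshape(B, C, h * w).transpose(0, 2, 1)  # [B, N, C]
        if self.use_attention:
            # channel self-attention: tokens act as features of channel queries
            tc = tokens.transpose(0, 2, 1)  # [B, C, N]
            tc = tc + self.csa(tc, tc, tc, record=record)
            tokens = self.csa_norm(tc.transpose(0, 2, 1))
            # spatial self-attention over the N_coord positions
            tokens = self.ssa_norm(tokens + self.ssa(tokens, tokens, tokens,
                                                     record=record))
        return tokens
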