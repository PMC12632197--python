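"""The SC-informed module: a prompt-conditioned cross-attention decoder.

The expression token (the prompt) and the image tokens are fused over
``rounds`` iterations.  Each round runs, on the query stream:

1. self-attention (residual + layer norm);
2. *expr2img* cross-attention — query = expression token + self-attention
   output, key = value = image tokens;
3. an MLP (residual + layer norm; one MLP per round);
4. *img2expr* cross-attention updating the image stream — query = image
   tokens, key = expression token + MLP output, value = MLP output.

The round-1 query is initialised with the expression token alone; the
round-2 query re-injects the intermediate MLP output (the expression token
re-enters inside expr2img).  After the final round a terminal expr2img
attention makes the expression embedding the dominant signal in the output
query token.  Self-attention, the in-loop expr2img and img2expr share
weights across rounds; with the terminal expr2img and the per-round MLPs
this realises one self-attention, two expr2img, one img2expr and two MLP
modules.

``cross_gate`` multiplies every cross-attention output before its residual
add (0 disables all cross-modal flow, leaving residual paths only);
``kv_perm`` applies a seeded token permutation to cross-attention keys and
values (the scramble ablation).  The identity permutation reproduces the
default computation exactly.
"""

from __future__ import annotations

import numpy as np

from ..nn import (Module, LayerNorm, Mlp, MultiheadAttention, Tensor, concat)
from .config import ModelConfig


class SCInformedDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, h = cfg.d_att, cfg.n_heads
        self.rounds = cfg.decoder_rounds
        self.self_attn = MultiheadAttention(d, h, rng)
        self.self_norm = LayerNorm(d)
        self.expr2img = MultiheadAttention(d, h, rng)
        self.expr2img_norm = LayerNorm(d)
        self.mlps = [Mlp(d, cfg.mlp_hidden, d, rng) for _ in range(self.rounds)]
        self.mlp_norms = [LayerNorm(d) for _ in range(self.rounds)]
        self.img2expr = MultiheadAttention(d, h, rng)
        self.img2expr_norm = LayerNorm(d)
        self.final_expr2img = MultiheadAttention(d, h, rng)
        self.final_norm = LayerNorm(d)

    def __call__(self, img: Tensor, expr: Tensor, cross_gate: float = 1.0,
                 kv_perm: np.ndarray | None = None,
                 hooks: dict | None = None) -> Tensor:
        q = expr  # round-1 output queries: the expression embedding alone
        for r in range(self.rounds):
            if hooks is not None:
                hooks.setdefault("round_queries", []).append(q.data.copy())
            sa = self.self_norm(q + self.self_attn(q, q, q, record=hooks))
            qq = expr + sa
            x = self.expr2img(qq, img, img, kv_perm=kv_perm, record=hooks)
            x = self.expr2img_norm(qq + cross_gate * x)
            m = self.mlp_norms[r](x + self.mlps[r](x))
            gi = self.img2expr(img, expr + m, m, record=hooks)
            img = self.img2expr_norm(img + cross_gate * gi)
            q = m  # round-(r+1) queries: the intermediate MLP output
        qq = expr + q
        out = self.final_expr2img(qq, img, img, kv_perm=kv_perm, record=hooks)
        return self.final_norm(qq + cross_gate * out)


class ConcatDecoder(Module):
    """Ablation: mean image token and expression token concatenated -> MLP."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.d_att
        self.mlp = Mlp(2 * d, cfg.mlp_hidden, d, rng)
        self.norm = LayerNorm(d)

    def __call__(self, img: Tensor, expr: Tensor, **_ignored) -> Tensor:
        img_mean = img.mean(axis=1, keepdims=True)  # [B,1,d]
        fused = concat([img_mean, expr], axis=-1)
        return self.norm(self.mlp(fused))
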