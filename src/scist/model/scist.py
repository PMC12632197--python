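"""The full SciSt network and its ablation variants.

The default model encodes the patch into N_coord image tokens and the IE
prior into one expression token, fuses them with the SC-informed
cross-attention decoder, and regresses the N_G-gene expression vector from
the output query token through a single affine head.

Variants (``ModelConfig.variant``):

- ``random_ie``        IE replaced by seeded standard-normal noise per spot;
- ``cellratio_noise``  mixture weights Dirichlet-perturbed before mixing;
- ``plain_resnet34``   image encoder without the CSA/SSA attention blocks;
- ``concat``           decoder replaced by concat(mean image token, expr
                       token) -> MLP;
- ``deep3``            three decoder rounds instead of two;
- ``cross_gate_zero``  all cross-attention outputs multiplied by zero;
- ``scramble_kv``      cross-attention keys/values token-permuted with a
                       seeded permutation, redrawn per batch.
"""

from __future__ import annotations

import json
import zlib

import numpy as np

from ..nn import Module, Linear, Tensor
from ..celltypes import DEAD
from .config import ModelConfig, VARIANTS
from .decoder import SCInformedDecoder, ConcatDecoder
from .encoders import ExprEncoder, ImageEncoder, normalize_patches

__all__ = ["SciStModel", "make_variant", "transform_ie", "normalize_patches"]


class SciStModel(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.image_encoder = ImageEncoder(cfg, rng)
        self.expr_encoder = ExprEncoder(cfg, rng)
        if cfg.variant == "concat":
            self.decoder = ConcatDecoder(cfg, rng)
        else:
            self.decoder = SCInformedDecoder(cfg, rng)
        self.head = Linear(cfg.d_att, cfg.n_genes, rng)
        self._perm_rng = np.random.default_rng((cfg.seed, 0x5C15))

    @property
    def cross_gate(self) -> float:
        return 0.0 if self.cfg.variant == "cross_gate_zero" else 1.0

    def _batch_perm(self) -> np.ndarray | None:
        if self.cfg.variant != "scramble_kv":
            return None
        return self._perm_rng.permutation(self.cfg.n_coord)

    def forward(self, images: np.ndarray | Tensor, ie: np.ndarray | Tensor,
                hooks: dict | None = None,
                kv_perm: np.ndarray | None = None) -> Tensor:
        """Normalised patches [B,3,H,W] + IE [B,N_G] -> predictions [B,N_G]."""
        x = images if isinstance(images, Tensor) else Tensor(images)
        e = ie if isinstance(ie, Tensor) else Tensor(ie)
        if e.shape[-1] != self.cfg.n_genes:
            raise ValueError(f"IE width {e.shape[-1]} does not match the "
                             f"model gene panel ({self.cfg.n_genes})")
        if kv_perm is None:
            kv_perm = self._batch_perm()
        img_tok = self.image_encoder(x, record=hooks)
        expr_tok = self.expr_encoder(e)
        if hooks is not None:
            hooks["image_tokens"] = img_tok.data.copy()
            hooks["expr_token"] = expr_tok.data.copy()
        out_tok = self.decoder(img_tok, expr_tok, cross_gate=self.cross_gate,
                               kv_perm=kv_perm, hooks=hooks)
        B = out_tok.shape[0]
        return self.head(out_tok.reshape(B, out_tok.shape[-1]))

    __call__ = forward

    def predict(self, patches: np.ndarray, ie: np.ndarray,
                batch_size: int = 64) -> np.ndarray:
        """Inference on raw uint8 patches [N,H,W,3]; returns [N, N_G]."""
        self.eval()
        dt = self.dtype
        ie = np.atleast_2d(np.asarray(ie)).astype(dt)
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        out = []
        for i in range(0, len(patches), batch_size):
            x = normalize_patches(patches[i:i + batch_size]).astype(dt)
            out.append(self.forward(x, ie[i:i + batch_size]).data)
        return np.concatenate(out, axis=0).astype(np.float64)

    # -- checkpointing -----------------------------------------------------
    def save_checkpoint(self, path: str, gene_panel: list[str] | None = None,
                        reference_hash: str = "", target_sum: float = 0.0,
                        ) -> None:
        meta = {"config": self.cfg.to_dict(),
                "gene_panel": gene_panel or [],
                "reference_hash": reference_hash,
                "target_sum": target_sum}
        arrays = self.state_arrays()
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load_checkpoint(cls, path: str) -> tuple["SciStModel", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        model = cls(ModelConfig.from_dict(meta["config"]))
        model.load_state_arrays(arrays)
        return model, meta


def make_variant(cfg: ModelConfig) -> SciStModel:
    """Instantiate the model for ``cfg.variant`` (error lists valid names)."""
    if cfg.variant not in VARIANTS:
        raise ValueError(f"unknown variant {cfg.variant!r}; "
                         f"valid: {list(VARIANTS)}")
    return SciStModel(cfg)


def _spot_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng((seed, zlib.crc32(key.encode())))


def transform_ie(ie: np.ndarray, cfg: ModelConfig, spot_keys: list[str],
                 counts=None, refs=None) -> np.ndarray:
    """Apply the IE-level ablations; identity for architecture variants.

    ``random_ie`` replaces each spot's IE with standard-normal noise keyed by
    (model seed, spot id), so a spot sees the same noise every epoch.
    ``cellratio_noise`` mixes each spot's cell-ratio weights with a seeded
    flat-Dirichlet draw (fraction ``cfg.cellratio_noise_scale``) and
    recomposes the prior from the reference panel.
    """
    ie = np.asarray(ie, dtype=float)
    if cfg.variant == "random_ie":
        out = np.empty_like(ie)
        for i, key in enumerate(spot_keys):
            out[i] = _spot_rng(cfg.seed, key).standard_normal(ie.shape[1])
        return out
    if cfg.variant == "cellratio_noise":
        if counts is None or refs is None:
            raise ValueError("cellratio_noise needs per-spot counts and a "
                             "reference panel")
        from ..initial_expression import compute_weights
        lam = cfg.cellratio_noise_scale
        types = refs.cell_types
        mat = np.stack([refs.vectors[t] for t in types])  # [T, N_G]
        out = np.empty_like(ie)
        for i, (key, c) in enumerate(zip(spot_keys, counts)):
            w, _ = compute_weights(c, types)
            pi = np.array([w[t] for t in types])
            noise = _spot_rng(cfg.seed, key).dirichlet(np.ones(len(types)))
            out[i] = ((1 - lam) * pi + lam * noise) @ mat
        return out
    return ie
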