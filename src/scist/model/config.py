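"""Model configuration: architecture dimensions, iteration count, variants."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

VARIANTS = ("scist", "random_ie", "cellratio_noise", "plain_resnet34",
            "concat", "deep3", "cross_gate_zero", "scramble_kv")


@dataclass
class ModelConfig:
    """Architecture dimensions and ablation-variant flags.

    ``d_att`` is the shared attention width (the channel width of the image
    encoder's final feature map), ``n_coord`` the number of spatial tokens
    (7x7 = 49 for the 34-layer residual backbone at 224x224 input), and
    ``decoder_rounds`` the number of decoder iterations (2 by default, 3 for
    the deepened ablation).  All randomness — weight init, noise variants,
    scramble permutations — flows from ``seed``.
    """

    n_genes: int
    d_att: int = 512
    n_coord: int = 49
    n_heads: int = 8
    mlp_hidden: int | None = None  # default 2 * d_att
    expr_hidden: int | None = None  # default d_att
    decoder_rounds: int = 2
    variant: str = "scist"
    seed: int = 0
    backbone: str = "resnet34"  # "resnet34" or "small"
    image_size: int = 224
    csa_heads: int = 1
    cellratio_noise_scale: float = 0.3
    small_channels: tuple[int, ...] = (16, 32)

    def __post_init__(self):
        if self.mlp_hidden is None:
            self.mlp_hidden = 2 * self.d_att
        if self.expr_hidden is None:
            self.expr_hidden = self.d_att
        if self.d_att % self.n_heads:
            raise ValueError(f"d_att={self.d_att} not divisible by "
                             f"n_heads={self.n_heads}")
        if self.decoder_rounds < 1:
            raise ValueError("decoder_rounds must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"valid: {list(VARIANTS)}")
        if self.variant == "deep3":
            self.decoder_rounds = 3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("small_channels"), list):
            d["small_channels"] = tuple(d["small_channels"])
        return cls(**d)


def small_config(n_genes: int, variant: str = "scist", seed: int = 0,
                 image_size: int = 64, d_att: int = 32) -> ModelConfig:
    """Desk-scale configuration: small CNN backbone, narrow attention.

    With the default three stride-2 convolutions plus the stride-2 stem the
    feature map of a 64x64 patch is 4x4, i.e. 16 tokens of width ``d_att``.
    """
    n_tokens = (image_size // 16) ** 2
    return ModelConfig(n_genes=n_genes, d_att=d_att, n_coord=n_tokens,
                       n_heads=4, decoder_rounds=2, variant=variant,
                       seed=seed, backbone="small", image_size=image_size)
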