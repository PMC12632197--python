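"""Architecture contracts of the network and its ablation variants.

These run on the desk-scale configuration (small trunk, d_att=32, 16
tokens); the full-size 49x512 token contract is exercised in the acceptance
suite.
"""

import numpy as np
import pytest

from scist.model import (ModelConfig, small_config, make_variant,
                         transform_ie, SciStModel)
from scist.model.encoders import ExprEncoder
from scist.nn import Tensor

N_G = 20


@pytest.fixture(scope="module")
def inputs():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (2, 3, 64, 64))
    ie = rng.normal(0, 1, (2, N_G))
    return x, ie


def build(variant="scist", seed=3):
    return make_variant(small_config(N_G, variant=variant, seed=seed))


class TestForwardContract:
    def test_token_shapes_and_output_length(self, inputs):
        x, ie = inputs
        model = build()
        model.eval()
        hooks: dict = {}
        out = model.forward(x, ie, hooks=hooks)
        assert out.shape == (2, N_G)
        assert hooks["image_tokens"].shape == (2, 16, 32)
        assert hooks["expr_token"].shape == (2, 1, 32)

    def test_round1_decoder_query_is_expression_embedding(self, inputs):
        x, ie = inputs
        model = build()
        model.eval()
        hooks: dict = {}
        model.forward(x, ie, hooks=hooks)
        assert np.array_equal(hooks["round_queries"][0], hooks["expr_token"])
        assert len(hooks["round_queries"]) == model.cfg.decoder_rounds

    def test_eval_forward_is_deterministic(self, inputs):
        x, ie = inputs
        model = build()
        model.eval()
        a = model.forward(x, ie).data
        b = model.forward(x, ie).data
        assert np.array_equal(a, b)

    def test_ie_width_mismatch_errors(self, inputs):
        x, _ = inputs
        model = build()
        with pytest.raises(ValueError, match="gene panel"):
            model.forward(x, np.zeros((2, N_G + 1)))

    def test_attention_rows_sum_to_one_at_every_site(self, inputs):
        x, ie = inputs
        model = build()
        model.eval()
        hooks: dict = {}
        model.forward(x, ie, hooks=hooks)
        sites = hooks["attention_weights"]
        # CSA + SSA + per-round (self, expr2img, img2expr) + terminal
        assert len(sites) == 2 + 3 * model.cfg.decoder_rounds + 1
        for w in sites:
            assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-9)

    def test_gradients_reach_every_submodule(self, inputs):
        x, ie = inputs
        model = build()
        model.train()
        out = model.forward(x, ie)
        (out * out).mean().backward()
        for p in model.parameters():
            assert p.grad is not None
        named = model.state_arrays()
        grads = {}
        for part in ("image_encoder", "expr_encoder", "decoder", "head"):
            sub = getattr(model, part)
            grads[part] = max(float(np.abs(p.grad).max())
                              for p in sub.parameters())
        assert all(g > 0 for g in grads.values()), grads
        assert named  # checkpoint map is non-empty


class TestExprEncoder:
    def test_zero_ie_with_zero_biases_gives_zero_embedding(self):
        cfg = small_config(N_G, seed=1)
        enc = ExprEncoder(cfg, np.random.default_rng(1))
        out = enc(Tensor(np.zeros((3, N_G))))
        assert np.allclose(out.data, 0.0, atol=1e-15)

    def test_hand_set_toy_weights_match_manual_affine_gelu(self):
        from scipy.special import erf
        cfg = ModelConfig(n_genes=2, d_att=4, n_coord=1, n_heads=1,
                          expr_hidden=3, backbone="small", image_size=16)
        enc = ExprEncoder(cfg, np.random.default_rng(0))
        W1 = np.arange(6, dtype=float).reshape(2, 3) / 10
        b1 = np.array([0.1, -0.2, 0.3])
        W2 = np.arange(12, dtype=float).reshape(3, 4) / 20
        b2 = np.array([0.0, 0.5, -0.5, 1.0])
        enc.fc1.weight.data, enc.fc1.bias.data = W1, b1
        enc.fc2.weight.data, enc.fc2.bias.data = W2, b2
        ie = np.array([[0.7, -1.3]])
        h = ie @ W1 + b1
        h = h * 0.5 * (1.0 + erf(h / np.sqrt(2)))
        expected = h @ W2 + b2
        assert np.allclose(enc(Tensor(ie)).data[0, 0], expected, atol=1e-12)


class TestVariants:
    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="random_ie"):
            ModelConfig(n_genes=4, variant="bogus")

    def test_scramble_with_identity_permutation_is_bitwise_default(self, inputs):
        x, ie = inputs
        default = build("scist")
        scram = build("scramble_kv")
        scram.load_state_arrays(default.state_arrays())
        default.eval(); scram.eval()
        ident = np.arange(scram.cfg.n_coord)
        a = default.forward(x, ie).data
        b = scram.forward(x, ie, kv_perm=ident).data
        assert np.array_equal(a, b)

    def test_scramble_with_random_permutation_changes_output(self, inputs):
        x, ie = inputs
        scram = build("scramble_kv")
        scram.eval()
        a = scram.forward(x, ie).data  # seeded draw 1
        b = scram.forward(x, ie, kv_perm=np.arange(scram.cfg.n_coord)).data
        assert not np.array_equal(a, b)

    def test_cross_gate_zero_output_independent_of_image(self, inputs):
        _, ie = inputs
        model = build("cross_gate_zero")
        model.eval()
        rng = np.random.default_rng(5)
        x1 = rng.normal(0, 1, (2, 3, 64, 64))
        x2 = rng.normal(5, 3, (2, 3, 64, 64))
        a = model.forward(x1, ie).data
        b = model.forward(x2, ie).data
        assert np.array_equal(a, b)

    def test_cross_gate_zero_image_gradient_exactly_zero(self, inputs):
        x, ie = inputs
        model = build("cross_gate_zero")
        model.eval()
        tx = Tensor(x, requires_grad=True)
        out = model.forward(tx, ie)
        out.sum().backward()
        assert tx.grad is None or np.all(tx.grad == 0)

    def test_deep3_runs_three_decoder_rounds(self, inputs):
        x, ie = inputs
        model = build("deep3")
        model.eval()
        hooks: dict = {}
        model.forward(x, ie, hooks=hooks)
        assert model.cfg.decoder_rounds == 3
        assert len(hooks["round_queries"]) == 3

    def test_concat_variant_has_expected_shape_and_uses_image(self, inputs):
        x, ie = inputs
        model = build("concat")
        model.eval()
        out = model.forward(x, ie)
        assert out.shape == (2, N_G)
        other = model.forward(x + 1.0, ie).data
        assert not np.array_equal(out.data, other)

    def test_plain_backbone_variant_skips_attention_blocks(self, inputs):
        x, ie = inputs
        model = build("plain_resnet34")
        assert not model.image_encoder.use_attention
        assert model.forward(x, ie).shape == (2, N_G)


class TestIETransforms:
    def test_random_ie_is_stable_per_spot_and_seeded(self):
        cfg = small_config(N_G, variant="random_ie", seed=9)
        ie = np.zeros((3, N_G))
        keys = ["a", "b", "c"]
        out1 = transform_ie(ie, cfg, keys)
        out2 = transform_ie(ie, cfg, keys)
        assert np.array_equal(out1, out2)
        assert not np.array_equal(out1[0], out1[1])
        # different model seed -> different noise
        cfg2 = small_config(N_G, variant="random_ie", seed=10)
        assert not np.array_equal(out1, transform_ie(ie, cfg2, keys))

    def test_cellratio_noise_stays_in_reference_hull(self, random_reference_panel):
        from scist.initial_expression import (CellTypeCounts,
                                              compose_initial_expression)
        from scist.celltypes import CELL_TYPES
        refs = random_reference_panel
        cfg = ModelConfig(n_genes=8, d_att=8, n_coord=4, n_heads=1,
                          variant="cellratio_noise", backbone="small")
        counts = [CellTypeCounts({CELL_TYPES[0]: 3, CELL_TYPES[1]: 1})]
        base = compose_initial_expression(counts[0], refs).values
        out = transform_ie(base[None], cfg, ["s"], counts=counts, refs=refs)
        stack = np.stack([refs.vectors[t] for t in refs.cell_types])
        assert np.all(out[0] >= stack.min(axis=0) - 1e-9)
        assert np.all(out[0] <= stack.max(axis=0) + 1e-9)
        assert not np.allclose(out[0], base)


def test_checkpoint_roundtrip(tmp_path, inputs):
    x, ie = inputs
    model = build()
    model.eval()
    before = model.forward(x, ie).data
    path = str(tmp_path / "ck.npz")
    model.save_checkpoint(path, gene_panel=[f"g{i}" for i in range(N_G)],
                          target_sum=1e4)
    loaded, meta = SciStModel.load_checkpoint(path)
    loaded.eval()
    assert meta["target_sum"] == 1e4
    assert np.array_equal(loaded.forward(x, ie).data, before)
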