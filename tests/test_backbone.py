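"""Backbone: patch embedding, windows, blocks, merging, accounting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import swinatt as sa
from swinatt.backbone import (
    PatchEmbed,
    PatchMerging,
    SwinBlock,
    WindowAttention,
    att_param_count,
)
from swinatt.nn import Tensor


@pytest.fixture
def desk_config():
    return sa.SwinConfig.desk()


class TestPatchEmbed:
    def test_stage1_grid_shape_for_full_input(self):
        cfg = sa.SwinConfig.from_variant("tiny", num_classes=1000)
        embed = PatchEmbed(cfg, np.random.default_rng(0))
        out = embed(np.zeros((2, 3, 224, 224)))
        assert out.shape == (2, 96, 56, 56)

    def test_shape_arithmetic_small(self):
        cfg = sa.SwinConfig(image_size=56, patch_size=4, embed_dim=24,
                            depths=(1,), heads=(2,), window_size=7,
                            att_stages=frozenset())
        embed = PatchEmbed(cfg, np.random.default_rng(0))
        assert embed(np.zeros((1, 3, 56, 56))).shape == (1, 24, 14, 14)

    def test_matches_per_patch_projection_loop(self, rng):
        cfg = sa.SwinConfig(image_size=8, patch_size=4, embed_dim=5,
                            depths=(1,), heads=(1,), window_size=2,
                            att_stages=frozenset())
        embed = PatchEmbed(cfg, np.random.default_rng(3))
        x = rng.normal(size=(1, 3, 8, 8))
        out = embed(x).data
        w = embed.proj.weight.data
        b = embed.proj.bias.data
        for gy in range(2):
            for gx in range(2):
                patch = x[0, :, 4 * gy:4 * gy + 4, 4 * gx:4 * gx + 4].reshape(-1)
                expected = w @ patch + b
                assert np.abs(out[0, :, gy, gx] - expected).max() < 1e-5

    def test_indivisible_image_rejected(self):
        cfg = sa.SwinConfig.desk()
        embed = PatchEmbed(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible"):
            embed(np.zeros((1, 3, 57, 57)))


class TestTokenPlumbing:
    def test_stage1_token_count(self):
        out = sa.flatten_tokens(np.zeros((2, 96, 56, 56)))
        assert out.shape == (2, 3136, 96)

    def test_shape_arithmetic(self):
        assert sa.flatten_tokens(np.zeros((1, 5, 2, 3))).shape == (1, 6, 5)

    def test_flatten_unflatten_bitwise_round_trip(self, rng):
        x = rng.normal(size=(2, 7, 4, 6))
        back = sa.unflatten_tokens(sa.flatten_tokens(x), (4, 6))
        assert np.array_equal(back.data, x)

    @given(st.integers(1, 3), st.integers(1, 6), st.integers(1, 5),
           st.integers(1, 5))
    def test_flatten_round_trip_property(self, b, c, h, w):
        x = np.arange(b * c * h * w, dtype=float).reshape(b, c, h, w)
        assert np.array_equal(
            sa.unflatten_tokens(sa.flatten_tokens(x), (h, w)).data, x)

    def test_window_partition_counts(self, rng):
        tokens = rng.normal(size=(1, 56 * 56, 3))
        windows = sa.window_partition(tokens, (56, 56), 7)
        assert windows.shape == (64, 49, 3)

    def test_window_partition_reverse_bitwise(self, rng):
        tokens = rng.normal(size=(2, 8 * 8, 5))
        windows = sa.window_partition(tokens, (8, 8), 4)
        back = sa.window_reverse(windows, (8, 8), 4)
        assert np.array_equal(back.data, tokens)

    def test_single_window_degenerate(self, rng):
        tokens = rng.normal(size=(1, 64, 2))
        assert sa.window_partition(tokens, (8, 8), 8).shape == (1, 64, 2)

    def test_indivisible_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="not divisible"):
            sa.window_partition(rng.normal(size=(1, 36, 2)), (6, 6), 4)


class TestWindowAttention:
    def test_single_token_equals_projected_value(self, rng):
        attn = WindowAttention(4, 1, 2, np.random.default_rng(0))
        x = rng.normal(size=(3, 1, 4))
        out = attn(Tensor(x)).data
        qkv_w, qkv_b = attn.qkv.weight.data, attn.qkv.bias.data
        v = (x @ qkv_w.T + qkv_b)[:, :, 8:]  # value third of qkv
        expected = v @ attn.proj.weight.data.T + attn.proj.bias.data
        assert np.abs(out - expected).max() < 1e-8

    def test_two_token_window_matches_closed_form(self, rng):
        attn = WindowAttention(2, 1, 1, np.random.default_rng(1))
        # 1x2 window: share one bias entry so the 2x2 score matrix is explicit
        attn._rel_index = np.zeros((2, 2), dtype=int)
        x = rng.normal(size=(1, 2, 2))
        qkv = x @ attn.qkv.weight.data.T + attn.qkv.bias.data
        q, k, v = qkv[0, :, :2], qkv[0, :, 2:4], qkv[0, :, 4:]
        scores = (q / np.sqrt(2)) @ k.T
        idx = attn._rel_index  # add relative position bias manually
        scores = scores + attn.relative_position_bias_table.data[idx, 0]
        weights = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights /= weights.sum(axis=1, keepdims=True)
        expected = (weights @ v) @ attn.proj.weight.data.T + attn.proj.bias.data
        out = attn(Tensor(x[:, :, :]))
        assert np.abs(out.data[0] - expected).max() < 1e-5

    def test_attention_rows_normalized(self, rng):
        from swinatt.nn import softmax

        scores = Tensor(rng.normal(size=(2, 3, 5, 5)))
        probs = softmax(scores, axis=-1).data
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_head_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            WindowAttention(5, 2, 2, np.random.default_rng(0))


class TestSwinBlock:
    def _zero_residual_branches(self, block):
        block.attn.proj.weight.data[:] = 0.0
        block.attn.proj.bias.data[:] = 0.0
        block.mlp.fc2.weight.data[:] = 0.0
        block.mlp.fc2.bias.data[:] = 0.0

    @pytest.mark.parametrize("shift", [0, 3])
    def test_zeroed_output_projections_make_identity(self, rng, shift):
        block = SwinBlock(6, (14, 14), 2, 7, shift, 4.0,
                          np.random.default_rng(0))
        self._zero_residual_branches(block)
        x = rng.normal(size=(2, 196, 6))
        out = block(Tensor(x)).data
        assert np.abs(out - x).max() < 1e-12

    def test_cyclic_shift_round_trip_identity(self, rng):
        from swinatt.nn import roll

        x = Tensor(rng.normal(size=(1, 8, 8, 3)))
        back = roll(roll(x, (-3, -3), (1, 2)), (3, 3), (1, 2))
        assert np.array_equal(back.data, x.data)

    def test_shape_preserved(self, rng):
        block = SwinBlock(96, (7, 7), 3, 7, 0, 4.0, np.random.default_rng(0))
        out = block(Tensor(rng.normal(size=(1, 49, 96))))
        assert out.shape == (1, 49, 96)

    def test_shifted_block_differs_from_unshifted(self, rng):
        kwargs = dict(dim=4, grid=(14, 14), num_heads=2, window_size=7,
                      mlp_ratio=2.0)
        plain = SwinBlock(shift=0, rng=np.random.default_rng(5), **kwargs)
        shifted = SwinBlock(shift=3, rng=np.random.default_rng(5), **kwargs)
        x = rng.normal(size=(1, 196, 4))
        assert not np.allclose(plain(Tensor(x)).data, shifted(Tensor(x)).data)


class TestPatchMerging:
    def test_grid_halves_channels_double(self, rng):
        merger = PatchMerging(96, (56, 56), np.random.default_rng(0))
        out = merger(Tensor(rng.normal(size=(1, 3136, 96))))
        assert out.shape == (1, 784, 192)

    def test_constant_field_stays_constant(self):
        merger = PatchMerging(3, (4, 4), np.random.default_rng(1))
        x = np.full((1, 16, 3), 1.7)
        out = merger(Tensor(x)).data
        assert np.allclose(out, out[:, :1, :])

    def test_matches_explicit_gather(self, rng):
        merger = PatchMerging(2, (2, 2), np.random.default_rng(2))
        x = rng.normal(size=(1, 4, 2))
        grid = x.reshape(2, 2, 2)
        gathered = np.concatenate([grid[0, 0], grid[1, 0],
                                   grid[0, 1], grid[1, 1]])
        mu, sd = gathered.mean(), gathered.std()
        normed = (gathered - mu) / np.sqrt(sd ** 2 + 1e-5)
        normed = normed * merger.norm.weight.data + merger.norm.bias.data
        expected = normed @ merger.reduction.weight.data.T
        out = merger(Tensor(x)).data
        assert np.abs(out[0, 0] - expected).max() < 1e-8

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError, match="even"):
            PatchMerging(4, (3, 4), np.random.default_rng(0))


class TestFullModel:
    def test_end_to_end_logit_shape(self, desk_config, rng):
        model = sa.SwinTransformer(desk_config, seed=0)
        logits = model(rng.normal(size=(2, 3, 56, 56)))
        assert logits.shape == (2, 3)

    def test_eval_forward_deterministic(self, desk_config, rng):
        model = sa.SwinTransformer(desk_config, seed=0)
        model.eval()
        x = rng.normal(size=(1, 3, 56, 56))
        a = model(x).data
        b = model(x).data
        assert np.array_equal(a, b)

    def test_no_attention_placement_is_noop_passthrough(self, rng):
        cfg = sa.SwinConfig.desk(att_stages=frozenset())
        model = sa.SwinTransformer(cfg, seed=0)
        x = Tensor(rng.normal(size=(1, 24, 14, 14)))
        assert model.apply_att(x, 1) is x

    def test_classify_matches_mean_then_affine_loop(self, desk_config, rng):
        model = sa.SwinTransformer(desk_config, seed=1)
        tokens = rng.normal(size=(2, 49, 48))
        out = model.classify(Tensor(tokens)).data
        gamma = model.norm.weight.data
        beta = model.norm.bias.data
        w, b = model.head.weight.data, model.head.bias.data
        for i in range(2):
            normed = np.empty_like(tokens[i])
            for t in range(49):
                row = tokens[i, t]
                normed[t] = gamma * (row - row.mean()) / np.sqrt(
                    row.var() + 1e-5) + beta
            expected = w @ normed.mean(axis=0) + b
            assert np.abs(out[i] - expected).max() < 1e-6

    def test_gradient_reaches_every_parameter(self, desk_config, rng):
        model = sa.SwinTransformer(desk_config, seed=3)
        model.train()
        from swinatt.train import cross_entropy

        x = rng.normal(size=(4, 3, 56, 56))
        loss = cross_entropy(model(x), np.array([0, 1, 2, 0]))
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_checkpoint_round_trip(self, desk_config, rng, tmp_path):
        model = sa.SwinTransformer(desk_config, seed=4)
        model.eval()
        x = rng.normal(size=(1, 3, 56, 56))
        before = model(x).data
        path = tmp_path / "model.ckpt"
        sa.save_checkpoint(path, model)
        restored = sa.load_checkpoint(path)
        restored.eval()
        assert np.array_equal(restored(x).data, before)
        assert restored.config == model.config


class TestParameterAccounting:
    @pytest.mark.parametrize("variant,millions", [("tiny", 28), ("small", 50),
                                                  ("base", 88), ("large", 197)])
    def test_variant_presets_round_to_published_millions(self, variant, millions):
        cfg = sa.SwinConfig.from_variant(variant, num_classes=1000,
                                         att_stages=frozenset())
        assert round(sa.count_parameters(cfg) / 1e6) == millions

    def test_closed_form_matches_instantiated_model(self):
        for att_stages in (frozenset(), frozenset({1}), frozenset({1, 2})):
            cfg = sa.SwinConfig.desk(att_stages=att_stages)
            model = sa.SwinTransformer(cfg, seed=0)
            assert model.num_parameters() == sa.count_parameters(cfg)

    def test_att_layer_delta_matches_hand_tally(self):
        base = sa.count_parameters(sa.SwinConfig.from_variant(
            "tiny", num_classes=1000, att_stages=frozenset()))
        with_att = sa.count_parameters(sa.SwinConfig.from_variant(
            "tiny", num_classes=1000, att_stages=frozenset({1})))
        # inp = oup = 96, mip = max(8, 96//32) = 8:
        # conv1 96*8, bn 2*8, conv_h/conv_w each 8*96 + 96
        hand = 96 * 8 + 16 + 2 * (8 * 96 + 96)
        assert with_att - base == hand
        assert att_param_count(96) == hand

    def test_placement_sets_increase_parameters_monotonically(self):
        counts = [sa.count_parameters(sa.SwinConfig.desk(att_stages=frozenset(p)))
                  for p in [(), (1,), (1, 2)]]
        assert counts[0] < counts[1] < counts[2]
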