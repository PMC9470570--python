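"""Backbone structure, attention modules, and the H=(1+M)F combination."""

import numpy as np
import pytest

from endoattn import model as M
from endoattn.nn import functional as F
from endoattn.nn.autograd import Tensor


class TestForwardShapes:
    def test_default_side_chain_matches_printed_sizes(self):
        sides = M.forward_shapes(M.BackboneConfig())
        assert sides[1] == 55    # first attention embedding point
        assert sides[2] == 28    # second
        assert sides[11] == 14   # third
        assert sides[12] == 7    # exit-flow downsampling
        assert sides == [109, 55, 28, 14] + [14] * 8 + [7, 7]

    def test_doubling_input_side_roughly_doubles_every_side(self):
        a = M.forward_shapes(M.BackboneConfig(input_side=441))
        b = M.forward_shapes(M.BackboneConfig(input_side=882))
        for sa, sb in zip(a, b):
            assert abs(sb - 2 * sa) <= 1

    def test_analytic_shapes_match_an_actual_forward(self, small_backbone_cfg):
        net = M.build_backbone(small_backbone_cfg, seed=0)
        x = np.zeros((1, 3, 128, 128))
        outs, logits = net.forward_blocks(Tensor(x))
        assert [o.shape[2] for o in outs] == M.forward_shapes(small_backbone_cfg)
        assert logits.shape == (1, small_backbone_cfg.num_classes)

    def test_too_small_input_is_a_configuration_error(self):
        with pytest.raises(M.ConfigError):
            M.BackboneConfig(input_side=32)


class TestBackboneStructure:
    def test_fourteen_modules_with_default_flows(self):
        net = M.build_backbone(M.BackboneConfig(
            input_side=128, channel_plan=M.ChannelPlan.small()))
        assert len(net.blocks) == 14
        middles = [b for b in net.blocks if isinstance(b, M._MiddleBlock)]
        assert len(middles) == 8
        # first and last modules carry no residual connection
        assert isinstance(net.blocks[0], M._Stem)
        assert isinstance(net.blocks[13], M._FinalBlock)

    def test_middle_block_preserves_shape(self, rng):
        block = M._MiddleBlock(6)
        from endoattn.nn import initialize_parameters
        initialize_parameters(block, 0)
        x = rng.normal(size=(2, 6, 9, 9))
        assert block(Tensor(x)).shape == x.shape

    def test_zero_input_forward_gives_two_class_scores(self, small_backbone_cfg):
        net = M.build_backbone(small_backbone_cfg, seed=1).eval()
        y = net(Tensor(np.zeros((1, 3, 128, 128))))
        assert y.shape == (1, 2)
        assert np.isfinite(y.data).all()


class TestAttentionCombine:
    def test_zero_mask_returns_trunk_unchanged(self, rng):
        f = rng.normal(size=(1, 2, 4, 4))
        h = M.attention_combine(f, np.zeros_like(f))
        assert np.array_equal(h, f)

    def test_unit_mask_doubles_trunk(self, rng):
        f = rng.normal(size=(1, 2, 4, 4))
        assert np.allclose(M.attention_combine(f, np.ones_like(f)), 2 * f)

    def test_pointwise_value(self):
        f = np.full((1, 1, 1, 1), 0.5)
        m = np.full((1, 1, 1, 1), 0.25)
        assert M.attention_combine(f, m)[0, 0, 0, 0] == pytest.approx(0.625)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            M.attention_combine(rng.normal(size=(1, 2, 4, 4)),
                                np.zeros((1, 2, 5, 5)))

    def test_out_of_range_mask_rejected(self, rng):
        f = rng.normal(size=(1, 1, 2, 2))
        with pytest.raises(ValueError):
            M.attention_combine(f, np.full_like(f, 1.5))


class TestAttentionModule:
    def test_output_shape_equals_input_shape(self, rng):
        mod = M.build_attention_module(4, 15, n_down=2, seed=0)
        x = rng.normal(size=(2, 4, 15, 15))
        assert mod(Tensor(x)).shape == x.shape

    def test_mask_values_strictly_inside_unit_interval(self, rng):
        mod = M.build_attention_module(4, 16, n_down=2, seed=1)
        mod.train()
        mod(Tensor(rng.normal(size=(4, 4, 16, 16))))
        m = mod.last_mask
        assert m.min() > 0.0 and m.max() < 1.0

    def test_forced_zero_mask_reduces_to_trunk(self, rng):
        mod = M.build_attention_module(3, 12, n_down=1, seed=2)
        M.force_zero_mask(mod)
        mod.eval()
        x = Tensor(rng.normal(size=(1, 3, 12, 12)))
        out = mod(x)
        trunk = mod.trunk(x)
        assert np.array_equal(out.data, trunk.data)

    def test_invalid_depth_is_a_configuration_error(self):
        with pytest.raises(M.ConfigError):
            M.AttentionModule(4, 3, n_down=4)  # 3 px cannot halve 4 times


class TestAssembly:
    def test_default_attention_derives_3_2_1_downsamplings(self):
        net = M.assemble_xception_ra(seed=0)
        assert [mod.n_down for mod in net.attention] == [3, 2, 1]
        assert net.attention_at(2).n_down == 3

    @pytest.mark.parametrize("positions,sides", [
        ((4, 12, 13), (14, 14, 7)),
        ((6, 8, 10), (14, 14, 14)),
        ((4, 8, 12), (14, 14, 14)),
        ((2, 3, 12), (55, 28, 14)),
    ])
    def test_table_variants_get_correct_local_sides(self, positions, sides):
        net = M.assemble_xception_ra(
            attn_cfg=M.AttentionConfig(positions=positions), seed=0)
        assert tuple(mod.local_side for mod in net.attention) == sides

    def test_position_beyond_block_count_rejected(self):
        with pytest.raises(M.ConfigError):
            M.AttentionConfig(positions=(2, 15))

    def test_inconsistent_downsample_counts_rejected(self, small_backbone_cfg):
        with pytest.raises(M.ConfigError):
            M.assemble_xception_ra(
                small_backbone_cfg,
                M.AttentionConfig(positions=(2, 3, 12),
                                  downsample_counts=(1, 2, 1)))

    def test_zero_masks_reproduce_trunk_only_network(self, small_backbone_cfg,
                                                     rng):
        net = M.assemble_xception_ra(small_backbone_cfg, seed=3)
        for mod in net.attention:
            M.force_zero_mask(mod)
        net.eval()
        x = Tensor(rng.normal(size=(1, 3, 128, 128)))
        logits_ra = net(x)
        # trunk-only composition with the identical remaining weights
        by_pos = dict(zip(net.attn_cfg.positions, net.attention))
        h = x
        for i, block in enumerate(net.backbone.blocks, start=1):
            h = block(h)
            if i in by_pos:
                h = by_pos[i].trunk(h)
        logits_trunk = net.backbone.head(F.global_avg_pool(h))
        assert np.array_equal(logits_ra.data, logits_trunk.data)

    def test_describe_is_json_ready(self, small_backbone_cfg):
        import json

        net = M.assemble_xception_ra(small_backbone_cfg, seed=0)
        desc = json.loads(json.dumps(M.describe(net)))
        assert len(desc["blocks"]) == 14
        assert [a["position"] for a in desc["attention"]] == [2, 3, 12]


class TestMaskGradientProperty:
    def test_constant_mask_scales_trunk_gradient(self, rng):
        # scalar probe: d(M*T)/dphi with M constant must equal M * dT/dphi
        mod = M.build_attention_module(2, 8, n_down=1, seed=4)
        M.force_zero_mask(mod)
        mod.mask_conv2.bias.data[...] = 0.0  # sigmoid(0) = 0.5 everywhere
        mod.eval()
        x = Tensor(rng.normal(size=(1, 2, 8, 8)))
        m, t = mod.mask_and_trunk(x)
        assert np.allclose(m.data, 0.5)
        mod.zero_grad()
        (Tensor(m.data) * t).sum().backward()
        masked = {id(p): p.grad.copy() for p in mod.trunk.parameters()}
        mod.zero_grad()
        mod.trunk(x).sum().backward()
        for p in mod.trunk.parameters():
            assert np.allclose(masked[id(p)], 0.5 * p.grad, atol=1e-12)

    def test_finite_difference_agreement(self, rng):
        mod = M.build_attention_module(4, 16, n_down=2, seed=5)
        probe = Tensor(rng.normal(size=(1, 4, 16, 16)))
        report = M.mask_gradient_property(mod, probe, n_params=10, seed=0)
        assert report["n_checked"] >= 10
        assert report["max_relative_error"] < 1e-4

    def test_backward_leaves_everything_finite(self, small_backbone_cfg, rng):
        net = M.assemble_xception_ra(small_backbone_cfg, seed=6)
        net.train()
        x = Tensor(rng.normal(size=(2, 3, 128, 128)))
        loss = F.cross_entropy_logits(net(x), np.array([0, 1]))
        loss.backward()
        for p in net.parameters():
            assert np.isfinite(p.data).all()
            assert p.grad is None or np.isfinite(p.grad).all()
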