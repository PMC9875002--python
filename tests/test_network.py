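"""Architecture blocks: shape traces, oracles, symmetries, ablations,
parameter accounting."""

import dataclasses

import numpy as np
import pytest

from dmffnet import nn
from dmffnet.autodiff import Tensor
from dmffnet.network import (CoordinateAttention, MultiscaleFusionBlock,
                             NetworkConfig, ParamCount, ResidualBlock,
                             SingleDenseAggregationBlock, build_network,
                             count_parameters)

RNG = np.random.default_rng(7)


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestResidualBlock:
    def test_zero_path_reduces_to_relu_identity(self):
        # with the whole residual path (incl. BN affine) zeroed, the block
        # is the identity mapping followed by ReLU
        block = ResidualBlock(8, ratio=4, rng=np.random.default_rng(0))
        block.eval()
        _zero_params(block)
        x = RNG.normal(size=(2, 8, 8, 8))
        out = block(Tensor(x)).data
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)

    def test_internal_width_trace(self):
        block = ResidualBlock(64, ratio=4, rng=np.random.default_rng(0))
        assert block.reduce.conv.weight.shape == (16, 64, 1, 1)
        assert block.conv.conv.weight.shape == (16, 16, 3, 3)
        assert block.expand.weight.shape == (64, 16, 1, 1)
        out = block(Tensor(RNG.normal(size=(1, 64, 32, 32))))
        assert out.shape == (1, 64, 32, 32)

    def test_output_nonnegative(self):
        block = ResidualBlock(8, ratio=4, rng=np.random.default_rng(1))
        out = block(Tensor(RNG.normal(size=(2, 8, 8, 8)))).data
        assert out.min() >= 0.0

    def test_channel_mismatch_rejected(self):
        block = ResidualBlock(8, ratio=4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="identity"):
            block(Tensor(RNG.normal(size=(1, 4, 8, 8))))


class TestSingleDenseAggregationBlock:
    @pytest.mark.parametrize("L", [4, 6, 8, 10])
    def test_aggregate_channels_scale_linearly_in_L(self, L):
        growth = 6
        block = SingleDenseAggregationBlock(3, L, growth, 16,
                                            np.random.default_rng(0))
        agg = block.aggregate(Tensor(RNG.normal(size=(1, 3, 8, 8))))
        assert agg.shape == (1, L * growth, 8, 8)

    def test_projected_output_width_and_grid(self):
        block = SingleDenseAggregationBlock(3, 10, 6, 16,
                                            np.random.default_rng(0))
        out = block(Tensor(RNG.normal(size=(2, 3, 8, 8))))
        assert out.shape == (2, 16, 8, 8)

    def test_minimum_two_layers(self):
        block = SingleDenseAggregationBlock(3, 2, 4, 8, np.random.default_rng(0))
        assert block.aggregate(Tensor(RNG.normal(size=(1, 3, 8, 8)))
                               ).shape[1] == 8
        with pytest.raises(ValueError, match="L >= 2"):
            SingleDenseAggregationBlock(3, 1, 4, 8, np.random.default_rng(0))

    def test_chain_uses_only_immediate_predecessor(self):
        # zeroing layer j's conv kills every later feature but leaves the
        # earlier concatenated features intact (no dense intra-links)
        block = SingleDenseAggregationBlock(3, 4, 5, 8, np.random.default_rng(2))
        block.eval()
        x = Tensor(RNG.normal(size=(1, 3, 8, 8)))
        before = block.aggregate(x).data
        _zero_params(block.layers[2])
        after = block.aggregate(x).data
        np.testing.assert_array_equal(before[:, :10], after[:, :10])
        assert not np.allclose(before[:, 10:], after[:, 10:])
        assert np.ptp(after[:, 10:15]) == 0.0  # zeroed layer is constant


class TestMultiscaleFusionBlock:
    def test_identical_inputs_fuse_identically_with_shared_weights(self):
        block = MultiscaleFusionBlock(8, None, 4, np.random.default_rng(0))
        block.proj2.conv.weight.data[...] = block.proj1.conv.weight.data
        block.eval()
        x = Tensor(RNG.normal(size=(1, 8, 16, 16)))
        O1, O2 = block(x, x)
        np.testing.assert_array_equal(O1.data, O2.data)

    def test_swapping_paths_swaps_outputs_with_shared_weights(self):
        block = MultiscaleFusionBlock(8, None, 4, np.random.default_rng(0))
        block.proj2.conv.weight.data[...] = block.proj1.conv.weight.data
        block.eval()
        a = Tensor(RNG.normal(size=(1, 8, 16, 16)))
        b = Tensor(RNG.normal(size=(1, 8, 16, 16)))
        O1, O2 = block(a, b)
        O1s, O2s = block(b, a)
        np.testing.assert_array_equal(O1.data, O2s.data)
        np.testing.assert_array_equal(O2.data, O1s.data)

    def test_carry_channel_bookkeeping(self):
        block = MultiscaleFusionBlock(8, prev_width=4, carry=5,
                                      rng=np.random.default_rng(0))
        assert block.proj1.conv.weight.shape[1] == 2 * 8 + 5
        prev = Tensor(RNG.normal(size=(1, 4, 32, 32)))
        O1, O2 = block(Tensor(RNG.normal(size=(1, 8, 16, 16))),
                       Tensor(RNG.normal(size=(1, 8, 16, 16))), prev, prev)
        assert O1.shape == (1, 8, 16, 16) and O2.shape == (1, 8, 16, 16)

    def test_grid_mismatch_rejected(self):
        block = MultiscaleFusionBlock(8, prev_width=4, carry=5,
                                      rng=np.random.default_rng(0))
        prev = Tensor(RNG.normal(size=(1, 4, 16, 16)))  # pools to 8x8, not 16x16
        with pytest.raises(ValueError, match="grid"):
            block(Tensor(RNG.normal(size=(1, 8, 16, 16))),
                  Tensor(RNG.normal(size=(1, 8, 16, 16))), prev, prev)


class TestCoordinateAttention:
    def test_axis_pooling_matches_brute_force(self):
        x = RNG.normal(size=(1, 3, 5, 4))
        t = Tensor(x)
        z_h = t.mean(axis=3, keepdims=True).data
        z_w = t.mean(axis=2, keepdims=True).data
        for c in range(3):
            for h in range(5):
                assert np.isclose(z_h[0, c, h, 0],
                                  sum(x[0, c, h, i] for i in range(4)) / 4)
            for w in range(4):
                assert np.isclose(z_w[0, c, 0, w],
                                  sum(x[0, c, j, w] for j in range(5)) / 5)

    def test_constant_input_gives_constant_descriptors_and_output(self):
        ca = CoordinateAttention(6, reduction=2, rng=np.random.default_rng(0))
        ca.eval()
        out = ca(Tensor(np.full((1, 6, 8, 8), 0.3))).data
        for c in range(6):
            assert np.ptp(out[0, c]) < 1e-12

    def test_attention_gates_lie_strictly_inside_unit_interval(self):
        ca = CoordinateAttention(6, reduction=2, rng=np.random.default_rng(1))
        ca.eval()
        x = np.abs(RNG.normal(size=(1, 6, 8, 8))) + 0.1
        out = ca(Tensor(x)).data
        ratio = out / x
        assert (ratio > 0.0).all() and (ratio < 1.0).all()


class TestNetworkConfig:
    def test_invalid_fields_named_in_errors(self):
        with pytest.raises(ValueError, match="n_levels"):
            NetworkConfig(n_levels=0)
        with pytest.raises(ValueError, match="sdab_layers"):
            NetworkConfig(sdab_layers=1)
        with pytest.raises(ValueError, match="base_width"):
            NetworkConfig(base_width=6, rb_bottleneck_ratio=4)

    def test_roundtrips_through_dict(self):
        cfg = NetworkConfig(sdab_layers=6, use_ca=False)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestBuildNetwork:
    def test_forward_shape_and_probability_range(self, tiny_config):
        net = build_network(tiny_config)
        net.eval()
        high = RNG.random((1, 1, 128, 128))
        low = high.reshape(1, 1, 64, 2, 64, 2).mean(axis=(3, 5))
        out = net.forward(high, low).data
        assert out.shape == (1, 1, 128, 128)
        assert (out > 0.0).all() and (out < 1.0).all()

    def test_fully_convolutional_in_input_size(self, tiny_config):
        net = build_network(tiny_config)
        net.eval()
        for size in (64, 128):
            high = RNG.random((1, 1, size, size))
            low = high.reshape(1, 1, size // 2, 2, size // 2, 2).mean(axis=(3, 5))
            assert net.forward(high, low).shape == (1, 1, size, size)

    def test_mismatched_resolutions_rejected(self, tiny_config):
        net = build_network(tiny_config)
        with pytest.raises(ValueError, match="half"):
            net.forward(RNG.random((1, 1, 64, 64)), RNG.random((1, 1, 64, 64)))

    def test_fusion_ablation_isolates_paths(self, tiny_config):
        # without cross-fusion, zeroing the high-res (path 2) input must
        # leave every O1 feature unchanged
        cfg = dataclasses.replace(tiny_config, use_mfb=False)
        net = build_network(cfg)
        net.eval()
        high = RNG.random((1, 1, 64, 64))
        low = high.reshape(1, 1, 32, 2, 32, 2).mean(axis=(3, 5))
        _, f_ref = net.forward(high, low, return_features=True)
        _, f_zero = net.forward(np.zeros_like(high), low, return_features=True)
        for lvl in range(1, cfg.n_levels + 1):
            np.testing.assert_array_equal(f_ref[f"O1_{lvl}"].data,
                                          f_zero[f"O1_{lvl}"].data)
        # sanity: with fusion on, the same probe must change O1
        net_full = build_network(tiny_config)
        net_full.eval()
        _, g_ref = net_full.forward(high, low, return_features=True)
        _, g_zero = net_full.forward(np.zeros_like(high), low,
                                     return_features=True)
        assert not np.allclose(g_ref["O1_1"].data, g_zero["O1_1"].data)

    @pytest.mark.parametrize("switch", ["use_rb", "use_sdab", "use_ca"])
    def test_ablation_switches_build_and_run(self, tiny_config, switch):
        cfg = dataclasses.replace(tiny_config, **{switch: False})
        net = build_network(cfg)
        net.eval()
        high = RNG.random((1, 1, 64, 64))
        low = high.reshape(1, 1, 32, 2, 32, 2).mean(axis=(3, 5))
        assert net.forward(high, low).shape == (1, 1, 64, 64)

    def test_every_parameter_receives_gradient(self, tiny_config):
        from dmffnet.objectives import dice_loss_graph
        net = build_network(tiny_config)
        high = RNG.random((2, 1, 64, 64))
        low = high.reshape(2, 1, 32, 2, 32, 2).mean(axis=(3, 5))
        target = (RNG.random((2, 1, 64, 64)) > 0.8).astype(float)
        loss = dice_loss_graph(net.forward(high, low), target)
        net.zero_grad()
        loss.backward()
        missing = [n for n, p in net.named_parameters() if p.grad is None]
        assert missing == []

    def test_weight_init_deterministic_in_seed(self, tiny_config):
        a = build_network(tiny_config)
        b = build_network(tiny_config)
        for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestParameterCounting:
    def test_single_conv_with_bias(self):
        conv = nn.Conv2d(1, 1, 3, np.random.default_rng(0), bias=True)
        assert sum(p.data.size for p in conv.parameters()) == 10

    def test_breakdown_sums_to_total(self, tiny_config):
        pc = count_parameters(build_network(tiny_config))
        assert sum(pc.per_module.values()) == pc.total
        assert pc.total > 0

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ParamCount(total=5, per_module={"a": 1})

    def test_count_is_affine_in_dense_chain_depth(self):
        totals = {
            L: count_parameters(build_network(NetworkConfig(sdab_layers=L))).total
            for L in (4, 6, 8, 10)
        }
        increments = {totals[L + 2] - totals[L] for L in (4, 6, 8)}
        assert len(increments) == 1

    def test_attention_ablation_removes_exactly_the_attention_params(self,
                                                                     tiny_config):
        full = count_parameters(build_network(tiny_config))
        no_ca = count_parameters(build_network(
            dataclasses.replace(tiny_config, use_ca=False)))
        diff = full.total - no_ca.total
        assert diff > 0
        assert full.per_module.keys() == no_ca.per_module.keys()
        assert (full.per_module["decoder"] - no_ca.per_module["decoder"]) == diff
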