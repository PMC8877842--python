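"""Architecture contract tests: SCB wiring, shape contract, parameter
accounting, variant parity, checkpoint round trip."""

import numpy as np
import pytest

import sssnet as s
from sssnet import nn
from sssnet.metrics import _loss_and_grad_fast


def _scb_spec(in_ch=8, p=8, a=8, c=8, sep=8, out=16):
    return s.SCBSpec(in_channels=in_ch, pointwise_width=p, asym_width=a,
                     conv3_width=c, sep_width=sep, out_width=out)


class TestSCB:
    def test_preserves_spatial_size(self):
        block = s.build_scb(_scb_spec(), seed=0)
        x = np.random.default_rng(0).normal(size=(1, 32, 32, 8)) \
            .astype(np.float32)
        assert block.forward(x).shape == (1, 32, 32, 16)

    def test_first_stage_concat_width(self):
        spec = _scb_spec(a=16)
        assert spec.da_channels == 32
        assert spec.db_channels == 32 + 8 + 8

    def test_hand_counted_parameters(self):
        # all widths 8, out 16, convs bias-free, BN has 2 per channel:
        #   1x1:        8*8          =   64
        #   1x3 + 3x1:  2 * 3*8*8    =  384
        #   3x3:        9*8*8        =  576
        #   sep:        9*8 + 8*8    =  136
        #   BN(DA=16) + BN(8) + BN(8): 2*(16+8+8) = 64
        #   bottleneck: 32*16        =  512
        #   BN(16):                  =   32
        expected = 64 + 384 + 576 + 136 + 64 + 512 + 32
        block = s.build_scb(_scb_spec(), seed=0)
        total = sum(p.size for _, p in block.named_parameters())
        assert total == expected

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError):
            s.SCBSpec(in_channels=8, pointwise_width=0, asym_width=8,
                      conv3_width=8, sep_width=8, out_width=8)

    def test_rejects_wrong_input_channels(self):
        block = s.build_scb(_scb_spec(in_ch=8), seed=0)
        with pytest.raises(ValueError, match="channels"):
            block.forward(np.zeros((1, 16, 16, 5), dtype=np.float32))

    def test_branches_share_spatial_dims_via_output(self):
        # concatenation is only well-defined if KA/KB/L/F agree spatially;
        # a successful forward on odd sizes certifies same-padding branches
        block = s.build_scb(_scb_spec(), seed=0)
        out = block.forward(np.zeros((1, 15, 21, 8), dtype=np.float32))
        assert out.shape[1:3] == (15, 21)


class TestNetwork:
    @pytest.mark.parametrize("variant", ["residual", "dense"])
    @pytest.mark.parametrize("hw", [(8, 8), (16, 24), (64, 64)])
    def test_shape_contract(self, variant, hw):
        net = s.build_network(s.small_spec(variant), seed=0)
        h, w = hw
        x = np.zeros((1, h, w, 3), dtype=np.float32)
        assert net.forward(x, training=False).shape == (1, h, w, 5)

    def test_rejects_indivisible_input(self):
        net = s.build_network(s.small_spec(), seed=0)
        with pytest.raises(ValueError, match="divisible by 8"):
            net.forward(np.zeros((1, 20, 20, 3), dtype=np.float32))

    def test_bottleneck_is_one_eighth(self):
        net = s.build_network(s.small_spec(), seed=0)
        h = net.scb1.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
        h = net.scb2.forward(net.down1.forward(h))
        h = net.scb3.forward(net.down2.forward(h))
        e4 = net.scb4.forward(net.down3.forward(h))
        assert e4.shape[1:3] == (8, 8)

    def test_variants_have_equal_parameter_counts(self):
        n_res = s.count_trainable_parameters(
            s.build_network(s.small_spec("residual"))).total_trainable
        n_dense = s.count_trainable_parameters(
            s.build_network(s.small_spec("dense"))).total_trainable
        assert n_res == n_dense

    def test_parameter_count_independent_of_input_size(self):
        net = s.build_network(s.small_spec(), seed=0)
        before = s.count_trainable_parameters(net).total_trainable
        net.forward(np.zeros((1, 16, 16, 3), dtype=np.float32))
        net.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
        assert s.count_trainable_parameters(net).total_trainable == before

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError, match="4 SCB"):
            s.NetworkSpec(scb_specs=[_scb_spec()] * 3)
        with pytest.raises(ValueError, match="variant"):
            s.NetworkSpec(variant="bogus",
                          scb_specs=[_scb_spec(in_ch=3)] + [_scb_spec()] * 3)

    def test_gradient_reaches_every_parameter(self):
        """One optimisation step on a one-image batch must change every
        trainable tensor: no dead branch in either variant."""
        for variant in ("residual", "dense"):
            net = s.build_network(s.small_spec(variant), seed=0)
            rng = np.random.default_rng(0)
            x = rng.random((1, 16, 16, 3), dtype=np.float32)
            gt = np.eye(5, dtype=np.float32)[rng.integers(0, 5, (1, 16, 16))]
            params = list(net.named_parameters())
            before = {name: p.data.copy() for name, p in params}
            scores = net.forward(x, training=True)
            probs = nn.softmax(scores)
            _, gp = _loss_and_grad_fast(probs, gt, s.TverskyParams())
            net.backward(nn.softmax_backward(probs, gp))
            opt = nn.Adam([p for _, p in params], lr=1e-3)
            opt.step()
            unchanged = [name for name, p in params
                         if np.array_equal(before[name], p.data)]
            assert unchanged == [], f"{variant}: dead parameters {unchanged}"

    def test_yaml_round_trip(self):
        spec = s.reference_spec("residual")
        again = s.NetworkSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_checkpoint_round_trip(self, tmp_path):
        net = s.build_network(s.small_spec("dense"), seed=7)
        x = np.random.default_rng(1).random((1, 16, 16, 3), dtype=np.float32)
        ref = net.forward(x, training=False).copy()
        path = tmp_path / "ckpt.npz"
        s.save_checkpoint(net, path)
        loaded = s.load_checkpoint(path)
        assert loaded.spec == net.spec
        assert np.allclose(loaded.forward(x, training=False), ref)


class TestParameterReport:
    def test_single_conv_with_bias(self):
        layer = nn.Conv2d(3, 4, 1, 1, bias=True)
        total = layer.weight.size + layer.bias.size
        assert total == 3 * 4 + 4 == 16

    def test_two_layer_toy_net_counted_by_hand(self):
        from sssnet.model import _Block

        # conv 3x3 (2->3, no bias) + BN(3): 54 + 6 = 60
        class Toy(_Block):
            def __init__(self):
                self.conv = nn.Conv2d(2, 3, 3, 3)
                self.bn = nn.BatchNorm2d(3)

        rep_layers = list(Toy().named_parameters())
        assert sum(p.size for _, p in rep_layers) == 54 + 6

    def test_per_layer_sums_to_total(self):
        net = s.build_network(s.small_spec(), seed=0)
        rep = s.count_trainable_parameters(net, input_hw=(32, 32))
        assert rep.total_trainable == sum(n for _, n in rep.per_layer)
        assert rep.flops_per_forward > 0


class TestSoftmaxHead:
    def test_uniform_on_zero_scores(self):
        p = nn.softmax(np.zeros((2, 4, 4, 5), dtype=np.float32))
        assert np.allclose(p, 0.2, atol=1e-7)

    def test_saturation(self):
        scores = np.zeros((1, 2, 2, 5), dtype=np.float32)
        scores[..., 3] = 1000.0
        p = nn.softmax(scores)
        assert np.all(p[..., 3] > 0.999)

    def test_per_pixel_sums(self):
        p = nn.softmax(np.random.default_rng(0).normal(
            size=(1, 4, 4, 5)).astype(np.float32))
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
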