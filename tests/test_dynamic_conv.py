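"""ODConv attention/aggregation, C3_ODC, and GSConv."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from nodulite import nn
from nodulite.blocks import C3
from nodulite.boxes_and_losses import ConfigError
from nodulite.dynamic_conv import (
    C3_ODC, GSConv, ODConv, ODConvAttention, ODConvConfig, gs_shuffle_perm,
    odconv_attention, odconv_forward,
)
from nodulite.nn import Tensor


def plain_conv_oracle(x, kernel, pad):
    """Reference convolution: per-sample, per-output-channel correlate2d."""
    b, cin, h, w = x.shape
    cout = kernel.shape[0]
    out = np.zeros((b, cout, h, w), np.float32)
    for bi in range(b):
        for o in range(cout):
            acc = np.zeros((h + 2 * pad - kernel.shape[-1] + 1,) * 2, np.float64)
            for c in range(cin):
                acc += correlate2d(np.pad(x[bi, c], pad), kernel[o, c], mode="valid")
            out[bi, o] = acc
    return out


def ones_attention(b, cfg):
    k, n = cfg.kernel_size, cfg.n_kernels
    return ODConvAttention(
        Tensor(np.ones((b, k, k), np.float32)),
        Tensor(np.ones((b, cfg.in_channels), np.float32)),
        Tensor(np.ones((b, cfg.out_channels), np.float32)),
        Tensor(np.ones((b, n), np.float32)),
    )


class TestAttention:
    def test_zero_heads_give_half(self):
        cfg = ODConvConfig(8, 8, 3, n_kernels=2)
        layer = ODConv(cfg)
        for head in (layer.head_s, layer.head_c, layer.head_f, layer.head_w):
            head.weight.data[...] = 0.0
            head.bias.data[...] = 0.0
        att = layer.attention(Tensor(np.random.default_rng(0)
                                     .random((2, 8, 5, 5)).astype(np.float32)))
        for a in (att.alpha_s, att.alpha_c, att.alpha_f, att.alpha_w):
            np.testing.assert_allclose(a.numpy(), 0.5)

    def test_sigmoid_range_and_batch_permutation(self):
        rng = np.random.default_rng(1)
        layer = ODConv(ODConvConfig(4, 6, 3, n_kernels=3))
        x = rng.normal(size=(5, 4, 6, 6)).astype(np.float32)
        att = layer.attention(Tensor(x))
        for a in (att.alpha_s, att.alpha_c, att.alpha_f, att.alpha_w):
            assert np.all((a.numpy() > 0) & (a.numpy() < 1))
        perm = [3, 0, 4, 1, 2]
        att_p = layer.attention(Tensor(x[perm]))
        np.testing.assert_allclose(att_p.alpha_c.numpy(), att.alpha_c.numpy()[perm],
                                   atol=1e-6)

    def test_softmax_option_sums_to_one(self):
        layer = ODConv(ODConvConfig(4, 4, 3, n_kernels=4), kernel_softmax=True)
        att = layer.attention(Tensor(np.random.default_rng(2)
                                     .random((3, 4, 4, 4)).astype(np.float32)))
        np.testing.assert_allclose(att.alpha_w.numpy().sum(axis=1), 1.0, atol=1e-6)

    def test_channel_mismatch_raises(self):
        layer = ODConv(ODConvConfig(4, 4, 3))
        with pytest.raises(ValueError):
            layer.attention(Tensor(np.zeros((1, 5, 4, 4), np.float32)))


class TestForward:
    def test_degenerate_attention_equals_standard_conv_exactly(self):
        rng = np.random.default_rng(3)
        cfg = ODConvConfig(4, 6, 3, n_kernels=1)
        layer = ODConv(cfg)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        out = odconv_forward(x, layer.weight, ones_attention(2, cfg), cfg)
        ref = nn.conv2d(x, Tensor(layer.weight.data[0]), None, 1, 1)
        np.testing.assert_array_equal(out.numpy(), ref.numpy())

    def test_kernel_only_attention_reduces_to_dynamic_conv(self):
        # alpha_s = alpha_c = alpha_f = 1: output equals convolution with the
        # alpha_w-weighted kernel mixture
        rng = np.random.default_rng(4)
        cfg = ODConvConfig(3, 5, 3, n_kernels=3)
        layer = ODConv(cfg)
        aw = rng.random((2, 3)).astype(np.float32)
        att = ones_attention(2, cfg)
        att.alpha_w = Tensor(aw)
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        out = odconv_forward(Tensor(x), layer.weight, att, cfg)
        for bi in range(2):
            mixed = np.tensordot(aw[bi], layer.weight.data, axes=(0, 0))
            ref = plain_conv_oracle(x[bi : bi + 1], mixed, 1)
            np.testing.assert_allclose(out.numpy()[bi : bi + 1], ref, atol=1e-5)

    def test_matches_aggregated_kernel_oracle_on_random_configs(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            cin = int(rng.integers(1, 9))
            cout = int(rng.integers(1, 9))
            n = int(rng.integers(1, 4))
            hw = int(rng.integers(3, 9))
            cfg = ODConvConfig(cin, cout, 3, n_kernels=n)
            layer = ODConv(cfg)
            b = int(rng.integers(1, 3))
            x = rng.normal(size=(b, cin, hw, hw)).astype(np.float32)
            att = layer.attention(Tensor(x))
            out = odconv_forward(Tensor(x), layer.weight, att, cfg)
            # oracle: materialize the aggregated kernel explicitly per sample
            for bi in range(b):
                agg = np.zeros((cout, cin, 3, 3), np.float64)
                for i in range(n):
                    agg += (att.alpha_w.numpy()[bi, i]
                            * att.alpha_f.numpy()[bi][:, None, None, None]
                            * att.alpha_c.numpy()[bi][None, :, None, None]
                            * att.alpha_s.numpy()[bi][None, None]
                            * layer.weight.data[i])
                ref = plain_conv_oracle(x[bi : bi + 1], agg.astype(np.float32), 1)
                np.testing.assert_allclose(out.numpy()[bi : bi + 1], ref,
                                           atol=1e-5, err_msg=f"trial {trial}")

    def test_attention_kernel_shape_mismatch_raises(self):
        cfg = ODConvConfig(4, 4, 3, n_kernels=2)
        layer = ODConv(cfg)
        bad = ones_attention(1, cfg)
        bad.alpha_c = Tensor(np.ones((1, 3), np.float32))
        with pytest.raises(ValueError):
            odconv_forward(Tensor(np.zeros((1, 4, 5, 5), np.float32)),
                           layer.weight, bad, cfg)


class TestC3ODC:
    def test_output_shape_matches_standard_c3(self):
        nn.seed_init(0)
        x = Tensor(np.random.default_rng(0).normal(size=(2, 16, 12, 12))
                   .astype(np.float32))
        std = C3(16, 16, 2).eval()
        odc = C3_ODC(16, 16, 2, n_kernels=2).eval()
        assert odc(x).shape == std(x).shape == (2, 16, 12, 12)

    def test_degenerate_odconv_matches_standard_c3(self):
        """With N=1 and attentions forced to 1, C3_ODC equals a standard C3
        carrying the same weights."""
        rng = np.random.default_rng(7)
        nn.seed_init(1)
        std = C3(8, 8, 1).eval()
        nn.seed_init(1)
        odc = C3_ODC(8, 8, 1, n_kernels=1, replace_1x1=False).eval()
        # copy shared weights; overwrite the ODConv kernel with the C3 conv's
        for name in ("cv1", "cv2", "cv3"):
            getattr(odc, name).conv.weight.data[...] = \
                getattr(std, name).conv.weight.data
        odc.m[0].cv1.conv.weight.data[...] = std.m[0].cv1.conv.weight.data
        odc.m[0].cv2.od.weight.data[0] = std.m[0].cv2.conv.weight.data
        layer = odc.m[0].cv2.od
        layer.attention = lambda x: ones_attention(x.shape[0], layer.cfg)
        x = Tensor(rng.normal(size=(2, 8, 10, 10)).astype(np.float32))
        np.testing.assert_allclose(odc(x).numpy(), std(x).numpy(), atol=1e-6)

    def test_gradient_reaches_every_attention_head(self):
        nn.seed_init(2)
        block = C3_ODC(8, 8, 1, n_kernels=2)
        x = Tensor(np.random.default_rng(8).normal(size=(2, 8, 8, 8))
                   .astype(np.float32))
        block(x).sum().backward()
        layer = block.m[0].cv2.od
        heads = {"s": layer.head_s, "c": layer.head_c,
                 "f": layer.head_f, "w": layer.head_w}
        for name, head in heads.items():
            assert head.weight.grad is not None, name
            assert np.abs(head.weight.grad).max() > 0, name

    def test_head_gradient_against_finite_differences(self):
        nn.seed_init(3)
        block = C3_ODC(4, 4, 1, n_kernels=2).eval()
        rng = np.random.default_rng(9)
        x_np = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        layer = block.m[0].cv2.od
        for head in (layer.head_s, layer.head_c, layer.head_f, layer.head_w):
            for p in block.parameters():
                p.grad = None
            block(Tensor(x_np)).sum().backward()
            g = head.weight.grad[0, 0]
            eps = 1e-2
            orig = head.weight.data[0, 0]
            head.weight.data[0, 0] = orig + eps
            lp = block(Tensor(x_np)).sum().item()
            head.weight.data[0, 0] = orig - eps
            lm = block(Tensor(x_np)).sum().item()
            head.weight.data[0, 0] = orig
            fd = (lp - lm) / (2 * eps)
            assert g == pytest.approx(fd, rel=0.25, abs=5e-3)


class TestGSConv:
    def test_shapes_and_stride(self):
        nn.seed_init(4)
        x = Tensor(np.random.default_rng(0).normal(size=(2, 16, 16, 16))
                   .astype(np.float32))
        assert GSConv(16, 32, 3, 1).eval()(x).shape == (2, 32, 16, 16)
        assert GSConv(16, 32, 3, 2).eval()(x).shape == (2, 32, 8, 8)

    def test_odd_channels_rejected(self):
        with pytest.raises(ConfigError):
            GSConv(16, 33)

    def test_shuffle_is_a_permutation_with_inverse(self):
        perm = gs_shuffle_perm(16)
        assert sorted(perm) == list(range(16))
        inv = np.argsort(perm)
        np.testing.assert_array_equal(perm[inv], np.arange(16))
        # applying the shuffle only reorders channel slices
        nn.seed_init(5)
        layer = GSConv(8, 16, 3).eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 8, 6, 6))
                   .astype(np.float32))
        a = layer.conv(x)
        b = layer.dw(a)
        unshuffled = np.concatenate([a.numpy(), b.numpy()], axis=1)
        shuffled = layer(x).numpy()
        np.testing.assert_array_equal(shuffled, unshuffled[:, perm])

    def test_parameter_count_below_standard_conv(self):
        std = nn.Conv2d(64, 128, 3, bias=False)
        gs = GSConv(64, 128, 3)
        assert std.weight.data.size == 73728
        n_gs = sum(p.data.size for p in gs.parameters())
        assert n_gs < 73728


def test_odconv_parameter_count_matches_hand_count():
    """N x (dense kernel) + attention trunk/heads, for one frozen config."""
    cfg = ODConvConfig(8, 16, 3, n_kernels=2, reduction_ratio=4)  # hidden 16
    layer = ODConv(cfg)
    n = sum(p.data.size for p in layer.parameters())
    kernels = 2 * 16 * 8 * 9                    # 2304
    fc = 8 * 16 + 16                            # 144
    heads = (16 * 9 + 9) + (16 * 8 + 8) + (16 * 16 + 16) + (16 * 2 + 2)
    assert n == kernels + fc + heads == 3043


def test_odconv_functional_api():
    layer = ODConv(ODConvConfig(4, 4, 3))
    x = Tensor(np.zeros((1, 4, 5, 5), np.float32))
    att = odconv_attention(x, layer)
    out = odconv_forward(x, layer.weight, att, layer.cfg)
    assert out.shape == (1, 4, 5, 5)
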