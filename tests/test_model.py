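"""Network architecture contracts: blocks, shapes, gradients, complexity."""

import numpy as np
import pytest

from cordseg.loss import focal_loss_and_grad, one_hot
from cordseg.model import (BottleneckBlock, ModelConfig, build_scs_net,
                           count_complexity, load_checkpoint,
                           save_checkpoint, vgg19_unet_parameter_count)
from cordseg.nn import BatchNorm2d, Conv2d


def oracle_conv(x, weight, stride=1, pad=0):
    """Direct-summation 2-D convolution oracle (no im2col)."""
    n, cin, h, w = x.shape
    cout, _, k, _ = weight.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    y = np.zeros((n, cout, ho, wo))
    for b in range(n):
        for co in range(cout):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[b, :, i * stride:i * stride + k,
                               j * stride:j * stride + k]
                    y[b, co, i, j] = (patch * weight[co]).sum()
    return y


def oracle_bn_eval(x, bn: BatchNorm2d):
    m = bn.running_mean[None, :, None, None]
    v = bn.running_var[None, :, None, None]
    g = bn.gamma.value[None, :, None, None]
    b = bn.beta.value[None, :, None, None]
    return g * (x - m) / np.sqrt(v + bn.eps) + b


class TestBottleneckBlock:
    def test_zero_weights_residual_passthrough(self):
        blk = BottleneckBlock(6, 3, 6, stride=1)
        for layer in blk.main.layers:
            if isinstance(layer, Conv2d):
                layer.weight.value[...] = 0.0
        x = np.random.default_rng(0).random((1, 6, 8, 8)).astype(np.float32)
        y = blk.forward(x, train=False)      # BN at identity init, eval mode
        assert np.allclose(y, x, atol=1e-6)

    def test_stride_two_halves_spatial_dims(self):
        blk = BottleneckBlock(4, 2, 8, stride=2)
        y = blk.forward(np.zeros((2, 4, 16, 16), np.float32))
        assert y.shape == (2, 8, 8, 8)

    def test_matches_hand_composed_layers(self):
        """Forward equals an independent composition of the primitives."""
        rng = np.random.default_rng(12)
        blk = BottleneckBlock(3, 2, 5, stride=1,
                              rng=np.random.default_rng(4))
        # randomize BN stats so the oracle is not trivially identity
        for layer in blk.main.layers + blk.shortcut.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = rng.normal(0, 0.1, layer.ch)
                layer.running_var[...] = rng.uniform(0.5, 1.5, layer.ch)
        x = rng.random((1, 3, 8, 8)).astype(np.float32)

        c1, b1, _, c2, b2, _, c3, b3 = blk.main.layers
        h = np.maximum(oracle_bn_eval(
            oracle_conv(x, c1.weight.value, pad=0), b1), 0)
        h = np.maximum(oracle_bn_eval(
            oracle_conv(h, c2.weight.value, pad=1), b2), 0)
        h = oracle_bn_eval(oracle_conv(h, c3.weight.value, pad=0), b3)
        sc, sb = blk.shortcut.layers
        s = oracle_bn_eval(oracle_conv(x, sc.weight.value, pad=0), sb)
        expected = np.maximum(h + s, 0)

        got = blk.forward(x, train=False)
        assert np.allclose(got, expected, atol=1e-4)


class TestForwardContract:
    def test_output_shape_and_probability_sums(self, tiny_model):
        x = np.random.default_rng(0).random((2, 1, 128, 128)).astype(np.float32)
        probs = tiny_model.forward(x)
        assert probs.shape == (2, 9, 128, 128)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-5
        assert probs.min() >= 0.0

    def test_fully_convolutional_at_64(self, tiny_model):
        x = np.random.default_rng(1).random((1, 1, 64, 64)).astype(np.float32)
        assert tiny_model.forward(x).shape == (1, 9, 64, 64)

    def test_indivisible_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 1, 100, 100), np.float32))

    def test_eval_forward_deterministic(self, tiny_model):
        x = np.random.default_rng(2).random((1, 1, 64, 64)).astype(np.float32)
        assert (tiny_model.forward(x) == tiny_model.forward(x)).all()

    def test_nearest_upsample_variant_runs(self):
        m = build_scs_net(ModelConfig(base_channels=8, upsample="nearest"),
                          seed=1)
        x = np.random.default_rng(3).random((1, 1, 32, 32)).astype(np.float32)
        assert m.forward(x).shape == (1, 9, 32, 32)

    def test_translation_covariance_one_stride_cycle(self):
        """Shifting the input by 16 px shifts the interior argmax by 16 px."""
        from cordseg import PhantomConfig, generate_phantom
        model = build_scs_net(ModelConfig(base_channels=8), seed=5)
        s = generate_phantom(PhantomConfig(image_size=64), seed=21)
        base = np.zeros((1, 1, 128, 128), np.float32)
        base[0, 0, 16:80, 16:80] = s.b0
        shifted = np.roll(base, 16, axis=3)
        am0 = model.forward(base).argmax(axis=1)[0]
        am1 = model.forward(shifted).argmax(axis=1)[0]
        interior = np.s_[34:94, 34:94]            # clears both borders
        agree = (np.roll(am0, 16, axis=1)[interior]
                 == am1[interior]).mean()
        assert agree > 0.98


class TestGradientsAndParameters:
    def test_every_parameter_receives_gradient(self, tiny_model):
        rng = np.random.default_rng(7)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        probs = tiny_model.forward(x, train=True)
        g = one_hot(rng.integers(0, 9, (2, 32, 32)))
        _, dp = focal_loss_and_grad(probs, g)
        for p in tiny_model.params():
            p.zero_grad()
        tiny_model.backward(dp)
        dead = [p.name for p in tiny_model.params() if np.all(p.grad == 0)]
        assert dead == []


class TestComplexity:
    def test_single_conv_parameter_count(self):
        conv = Conv2d(1, 8, k=3, bias=True)
        assert sum(p.value.size for p in conv.params()) == 80  # 3*3*1*8 + 8

    def test_doubling_base_quadruples_conv_params(self):
        # interior convs scale quadratically with width; the stem conv
        # (fixed 1 input channel) and head (fixed 9 outputs) scale linearly
        def interior_conv_params(base):
            m = build_scs_net(ModelConfig(base_channels=base), seed=0)
            convs = [p for p in m.params()
                     if p.name in ("conv.w", "convT.w")]
            return sum(p.value.size for p in convs[1:]) \
                - m.head.weight.value.size
        assert interior_conv_params(16) >= 4 * interior_conv_params(8)

    def test_lighter_than_vgg19_unet(self):
        params, _ = count_complexity(build_scs_net(ModelConfig(), seed=0))
        assert params < vgg19_unet_parameter_count()

    def test_flops_scale_with_input_area(self, tiny_model):
        _, macs128 = count_complexity(tiny_model, (128, 128))
        _, macs64 = count_complexity(tiny_model, (64, 64))
        assert macs128 == pytest.approx(4 * macs64, rel=1e-6)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_model.config
        x = np.random.default_rng(9).random((1, 1, 64, 64)).astype(np.float32)
        assert (loaded.forward(x) == tiny_model.forward(x)).all()
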