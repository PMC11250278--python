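"""Architecture contracts: CSP stages, pyramid-pooling attention, AFF fusion,
decoder outputs and whole-network shape/determinism/gradient-flow checks.

All tests use the reduced configuration; the full-size 512-px contract is
exercised by the acceptance suite.
"""

import numpy as np
import pytest

from earcount.network import (AFF, CSPStage, EarDensityNet, ModelConfig,
                              P2TBlock, PyramidPoolAttention, Tensor,
                              no_grad, tiny_config)
from earcount.network.layers import _tokens


def _x(rng, *shape):
    return Tensor(rng.random(shape).astype(np.float32))


class TestCSPStage:
    def test_halves_resolution_and_sets_channels(self, rng):
        stage = CSPStage(3, 16, 1, rng=rng)
        out = stage(_x(rng, 2, 3, 64, 64))
        assert out.shape == (2, 16, 32, 32)

    def test_zero_input_finite_output(self, rng):
        stage = CSPStage(8, 16, 2, rng=rng)
        out = stage(Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32)))
        assert np.isfinite(out.data).all()

    def test_channel_mismatch_raises(self, rng):
        stage = CSPStage(8, 16, 1, rng=rng)
        with pytest.raises(ValueError):
            stage(_x(rng, 1, 4, 16, 16))


class TestPyramidPoolAttention:
    def test_resolution_preserved(self, rng):
        block = P2TBlock(32, heads=4, rng=rng)
        out = block(_x(rng, 2, 32, 32, 32))
        assert out.shape == (2, 32, 32, 32)

    def test_kv_tokens_fewer_than_queries(self, rng):
        attn = PyramidPoolAttention(32, heads=4, pool_bins=(1, 2, 3, 6), rng=rng)
        xmap = _x(rng, 1, 32, 32, 32)
        kv = attn.pooled_tokens(xmap)
        assert kv.shape[1] == 1 + 4 + 9 + 36
        assert kv.shape[1] < 32 * 32

    def test_batch_independence(self, rng):
        block = P2TBlock(16, heads=4, rng=rng)
        block.eval()
        a = _x(rng, 1, 16, 8, 8)
        b = _x(rng, 1, 16, 8, 8)
        ab = block(Tensor(np.concatenate([a.data, b.data])))
        ba = block(Tensor(np.concatenate([b.data, a.data])))
        assert np.allclose(ab.data[0], ba.data[1], atol=1e-6)
        assert np.allclose(ab.data[1], ba.data[0], atol=1e-6)

    def test_heads_must_divide_channels(self, rng):
        with pytest.raises(ValueError):
            PyramidPoolAttention(30, heads=4, rng=rng)


class TestAFF:
    def test_identical_inputs_pass_through(self, rng):
        aff = AFF(16, rng=rng)
        aff.eval()
        a = _x(rng, 2, 16, 8, 8)
        out = aff(a, Tensor(a.data.copy()))
        assert np.allclose(out.data, a.data, atol=1e-6)

    def test_output_is_convex_combination(self, rng):
        aff = AFF(16, rng=rng)
        aff.eval()
        a = _x(rng, 2, 16, 8, 8)
        b = _x(rng, 2, 16, 8, 8)
        out = aff(a, b).data
        lo = np.minimum(a.data, b.data)
        hi = np.maximum(a.data, b.data)
        assert (out >= lo - 1e-6).all() and (out <= hi + 1e-6).all()

    def test_attention_weights_in_unit_interval(self, rng):
        aff = AFF(16, rng=rng)
        aff.eval()
        m = aff.attention(_x(rng, 1, 16, 8, 8)).data
        assert (m > 0).all() and (m < 1).all()

    def test_shape_mismatch_raises(self, rng):
        aff = AFF(16, rng=rng)
        with pytest.raises(ValueError):
            aff(_x(rng, 1, 16, 8, 8), _x(rng, 1, 16, 4, 4))


class TestModelConfig:
    def test_defaults_match_stated_architecture(self):
        cfg = ModelConfig()
        assert cfg.stage_channels == (64, 256, 512, 512)
        assert cfg.decoder_dilations == (1, 2, 3)
        assert cfg.output_stride == 1

    @pytest.mark.parametrize("bad", [
        dict(output_stride=3),
        dict(decoder_dilations=(0, 1)),
        dict(stage_channels=(64, 256, 512, 510)),  # not divisible by heads
        dict(density_activation="square"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)

    def test_roundtrip_through_dict(self):
        cfg = tiny_config(output_stride=2)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_pyramid_shapes(self, tiny_model, rng):
        with no_grad():
            feats = tiny_model.extract_pyramid(_x(rng, 1, 3, 64, 64))
        assert [f.shape for f in feats] == [
            (1, 16, 32, 32), (1, 32, 16, 16), (1, 64, 8, 8), (1, 64, 4, 4)]

    def test_output_contracts(self, tiny_model, rng):
        with no_grad():
            pair = tiny_model(_x(rng, 2, 3, 64, 64))
        assert pair.density.shape == (2, 1, 64, 64)
        assert pair.attention.shape == (2, 1, 64, 64)
        assert (pair.density.data >= 0).all()
        assert (pair.attention.data > 0).all() and (pair.attention.data < 1).all()
        assert pair.counts().shape == (2,)

    def test_output_stride_two(self, rng):
        model = EarDensityNet(tiny_config(output_stride=2), rng=0)
        with no_grad():
            pair = model(_x(rng, 1, 3, 64, 64))
        assert pair.density.shape == (1, 1, 32, 32)

    def test_indivisible_side_raises_with_padding_hint(self, tiny_model, rng):
        with pytest.raises(ValueError, match="pad by"):
            tiny_model(_x(rng, 1, 3, 60, 64))

    def test_eval_forward_is_deterministic(self, tiny_model, rng):
        tiny_model.eval()
        x = _x(rng, 1, 3, 64, 64)
        with no_grad():
            a = tiny_model(x).density.data
            b = tiny_model(x).density.data
        assert np.array_equal(a, b)

    def test_gradient_reaches_every_parameter(self, rng):
        model = EarDensityNet(tiny_config(), rng=0)
        model.train()
        pair = model(_x(rng, 2, 3, 64, 64))
        (pair.density.mean() + pair.attention.mean()).backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name

    def test_predict_density_pads_odd_sizes(self, tiny_model, rng):
        img = rng.random((70, 90, 3)).astype(np.float32)
        den = tiny_model.predict_density(img)
        assert den.shape == (70, 90)
        assert np.isfinite(den).all() and (den >= 0).all()

    def test_token_roundtrip_helper(self, rng):
        x = _x(rng, 2, 8, 4, 4)
        t = _tokens(x)
        assert t.shape == (2, 16, 8)
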