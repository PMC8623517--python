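"""Architecture contracts: block wiring, attention gating, path shapes,
whole-pipeline reconstruction."""

import numpy as np
import pytest

from wfsan.network import (
    AttentionGhostExtensionBlock,
    BlockSpec,
    GhostExtensionBlock,
    NetworkConfig,
    SpatialAttention,
    WFSAN,
    bicubic_upscale,
    reconstruct_bands,
    residual_base_from_image,
    super_resolve,
)
from wfsan.nn import DepthwiseConv2d
from wfsan.swt import split_bands, swt2_level1


def _spec(**kw):
    base = dict(kind="ghost", primary_filters=4, activation="relu")
    base.update(kw)
    return BlockSpec(**base)


class TestGhostBlock:
    def test_output_channels_double_primary(self, rng):
        blk = GhostExtensionBlock(4, _spec(), rng=rng)
        out = blk.forward(rng.random((2, 4, 6, 6)).astype(np.float32))
        assert out.shape == (2, 8, 6, 6)

    def test_identity_cheap_kernel_duplicates_primary(self, rng):
        blk = GhostExtensionBlock(4, _spec(), rng=rng)
        blk.cheap.W.value[...] = DepthwiseConv2d.identity_kernel(4, 3)
        out = blk.forward(rng.random((1, 4, 5, 5)).astype(np.float32))
        np.testing.assert_allclose(out[:, :4], out[:, 4:], atol=1e-7)

    def test_zero_input_zero_bias_gives_zero_output(self, rng):
        blk = GhostExtensionBlock(4, _spec(), rng=rng)
        blk.primary.b.value[...] = 0.0
        out = blk.forward(np.zeros((1, 4, 5, 5), dtype=np.float32))
        np.testing.assert_array_equal(out, 0.0)

    def test_channel_mismatch_rejected(self, rng):
        blk = GhostExtensionBlock(4, _spec(), rng=rng)
        with pytest.raises(ValueError):
            blk.forward(np.zeros((1, 5, 5, 5), dtype=np.float32))


class TestSpatialAttention:
    def test_constant_features_give_constant_map_in_unit_interval(self, rng):
        att = SpatialAttention(3, rng=rng)
        feats = np.full((1, 6, 8, 8), 2.5, dtype=np.float32)
        amap = att.forward(feats)
        assert amap.shape == (1, 1, 8, 8)
        assert amap.min() >= 0.0 and amap.max() <= 1.0
        assert np.ptp(amap[0, 0, 2:-2, 2:-2]) < 1e-6  # interior constant

    def test_map_always_in_unit_interval(self, rng):
        att = SpatialAttention(3, rng=rng)
        amap = att.forward(rng.normal(0, 50, (2, 5, 6, 6)).astype(np.float32))
        assert amap.min() >= 0.0 and amap.max() <= 1.0

    def test_zero_weights_with_bias_three_saturates_to_one(self, rng):
        att = SpatialAttention(3, bias=True, rng=rng)
        att.merge.W.value[...] = 0.0
        att.merge.b.value[...] = 3.0
        amap = att.forward(rng.random((1, 4, 5, 5)).astype(np.float32))
        np.testing.assert_allclose(amap, 1.0)

    def test_bias_free_by_default(self, rng):
        att = SpatialAttention(3, rng=rng)
        assert att.merge.b is None
        assert sum(p.size for p in att.params()) == 2 * 9


class TestAttentionGhostBlock:
    def test_unit_attention_reduces_to_ghost_block(self, rng):
        spec = _spec(kind="attention_ghost")
        blk = AttentionGhostExtensionBlock(4, spec, rng=np.random.default_rng(0))
        ghost = GhostExtensionBlock(4, _spec(), rng=np.random.default_rng(1))
        ghost.primary.W.value[...] = blk.primary.W.value
        ghost.primary.b.value[...] = blk.primary.b.value
        ghost.cheap.W.value[...] = blk.cheap.W.value
        x = rng.random((2, 4, 6, 6)).astype(np.float32)
        ones = np.ones((2, 1, 6, 6), dtype=np.float32)
        np.testing.assert_array_equal(
            blk.forward(x, attention_override=ones), ghost.forward(x)
        )

    def test_zero_attention_kills_cheap_half_only(self, rng):
        blk = AttentionGhostExtensionBlock(4, _spec(kind="attention_ghost"), rng=rng)
        x = rng.random((1, 4, 6, 6)).astype(np.float32)
        zeros = np.zeros((1, 1, 6, 6), dtype=np.float32)
        out = blk.forward(x, attention_override=zeros)
        ref = blk.forward(x, attention_override=np.ones_like(zeros))
        np.testing.assert_array_equal(out[:, 4:], 0.0)
        np.testing.assert_array_equal(out[:, :4], ref[:, :4])

    def test_output_channels(self, rng):
        blk = AttentionGhostExtensionBlock(4, _spec(kind="attention_ghost"), rng=rng)
        out = blk.forward(rng.random((1, 4, 6, 6)).astype(np.float32))
        assert out.shape == (1, 8, 6, 6)


class TestConfig:
    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(scale=5)

    def test_attention_in_approx_path_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(approx_block_kind="attention_ghost")

    def test_round_trips_through_dict(self):
        cfg = NetworkConfig(scale=3, base_filters=8)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    @pytest.mark.parametrize("scale", [2, 3, 4])
    def test_output_shapes_scale(self, rng, scale):
        m = WFSAN(NetworkConfig(scale=scale, base_filters=4, residual=False), seed=0)
        fa, fd = m.forward(
            rng.random((2, 1, 12, 12)).astype(np.float32),
            rng.random((2, 3, 12, 12)).astype(np.float32),
        )
        assert fa.shape == (2, 1, 12 * scale, 12 * scale)
        assert fd.shape == (2, 3, 12 * scale, 12 * scale)

    def test_channel_contracts_enforced(self, tiny_model, rng):
        good = rng.random((1, 1, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError):
            tiny_model.forward(rng.random((1, 2, 8, 8)).astype(np.float32),
                               rng.random((1, 3, 8, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            tiny_model.forward(good, rng.random((1, 4, 8, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            tiny_model.forward(good, rng.random((1, 3, 6, 6)).astype(np.float32))

    def test_forward_is_deterministic(self, tiny_model, rng):
        lca = rng.random((1, 1, 8, 8)).astype(np.float32)
        lcd = rng.random((1, 3, 8, 8)).astype(np.float32)
        fa1, fd1 = tiny_model.forward(lca, lcd)
        fa2, fd2 = tiny_model.forward(lca, lcd)
        np.testing.assert_array_equal(fa1, fa2)
        np.testing.assert_array_equal(fd1, fd2)

    def test_same_seed_same_weights(self):
        cfg = NetworkConfig(base_filters=4)
        s1 = WFSAN(cfg, seed=3).state_dict()
        s2 = WFSAN(cfg, seed=3).state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_residual_model_requires_anchor(self, rng):
        m = WFSAN(NetworkConfig(base_filters=4, residual=True), seed=0)
        with pytest.raises(ValueError, match="anchor"):
            m.forward(rng.random((1, 1, 8, 8)).astype(np.float32),
                      rng.random((1, 3, 8, 8)).astype(np.float32))

    def test_residual_model_starts_at_bicubic_anchor(self, rng):
        """Zero-initialized heads make the initial model reproduce
        bicubic upscaling exactly."""
        m = WFSAN(NetworkConfig(scale=2, base_filters=4, residual=True), seed=0)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        out = super_resolve(img, m)
        ref = np.clip(np.rint(bicubic_upscale(img, 2)), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out, ref)


class TestSuperResolve:
    def test_shape_and_dtype(self, rng):
        m = WFSAN(NetworkConfig(scale=4, base_filters=4, residual=False), seed=0)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        out = super_resolve(img, m)
        assert out.shape == (64, 64)
        assert out.dtype == np.uint8

    def test_multichannel_input_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="grayscale"):
            super_resolve(np.zeros((8, 8, 3), dtype=np.uint8), tiny_model)

    def test_scale_mismatch_rejected(self, tiny_model, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        with pytest.raises(ValueError):
            super_resolve(img, tiny_model, scale=3)

    def test_injected_bicubic_coefficients_reconstruct_bicubic(self, rng):
        """Feeding the sub-bands of the bicubic upscale through the
        reconstruction stage returns the bicubic upscale itself."""
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        up = bicubic_upscale(img, 2)
        fa, fd = split_bands(swt2_level1(up / 255.0))
        rec = reconstruct_bands(fa, fd, 255.0)
        assert np.abs(rec - up).max() < 1e-6
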