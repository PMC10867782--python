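"""Block-level reduction oracles and end-to-end properties of the generator."""

import numpy as np
import pytest

from tsegan import nn
from tsegan.generator import (ContentRevisor, NetworkConfig, ResidualFusion,
                              SpadeBlock, SpatialAttention,
                              TranslationGenerator, fuse_features,
                              standardize_channels)

RNG = np.random.default_rng(0)


class TestNetworkConfig:
    def test_global_must_be_twice_roi(self):
        with pytest.raises(ValueError):
            NetworkConfig(roi_size=128, global_size=512)

    def test_min_groups(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_groups=1)

    def test_desk_profile_parameter_budget(self):
        gen = TranslationGenerator(NetworkConfig.desk())
        assert gen.n_parameters() <= 1_000_000


class TestResidualFusion:
    def test_zero_weights_identity(self):
        rf = ResidualFusion(4, 3, np.random.default_rng(1))
        for p in rf.parameters():
            p.data[...] = 0.0
        for _, b in ((None, blk) for blk in rf.blocks):
            b.bn1.gamma.data[...] = 0.0  # kill conv+norm path entirely
            b.bn2.gamma.data[...] = 0.0
        x = nn.Tensor(RNG.normal(size=(1, 4, 8, 8)))
        np.testing.assert_allclose(rf(x).data, x.data, atol=1e-12)

    def test_shape_preserved_and_default_depth(self):
        cfg = NetworkConfig()
        assert cfg.n_resblocks == 9
        rf = ResidualFusion(4, cfg.n_resblocks, np.random.default_rng(1))
        assert len(rf.blocks) == 9
        x = nn.Tensor(RNG.normal(size=(2, 4, 8, 8)))
        assert rf(x).shape == x.shape


class TestSpadeBlock:
    def test_identity_modulation_returns_standardized_input(self):
        sb = SpadeBlock(4, 7, np.random.default_rng(2))
        for p in (sb.to_gamma.weight, sb.to_gamma.bias,
                  sb.to_beta.weight, sb.to_beta.bias):
            p.data[...] = 0.0
        x = nn.Tensor(RNG.normal(1.0, 2.0, size=(2, 4, 8, 8)))
        cond = nn.Tensor(RNG.normal(size=(2, 7, 8, 8)))
        out = sb.denormalize(x, cond).data
        np.testing.assert_allclose(out.mean(axis=(2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.var(axis=(2, 3)), 1.0, atol=1e-4)

    def test_output_reacts_to_conditioning_image(self):
        sb = SpadeBlock(4, 7, np.random.default_rng(3))
        x = nn.Tensor(RNG.normal(size=(1, 4, 8, 8)))
        cond1 = nn.Tensor(RNG.normal(size=(1, 7, 8, 8)))
        cond2 = nn.Tensor(cond1.data + RNG.normal(size=cond1.shape))
        delta = np.abs(sb(x, cond1).data - sb(x, cond2).data).max()
        assert delta > 0.0

    def test_resolution_mismatch_rejected(self):
        sb = SpadeBlock(4, 7, np.random.default_rng(4))
        with pytest.raises(ValueError):
            sb(nn.Tensor(np.zeros((1, 4, 8, 8))),
               nn.Tensor(np.zeros((1, 7, 4, 4))))


class TestSpatialAttention:
    def test_mask_range_and_shape(self):
        sa = SpatialAttention(np.random.default_rng(5))
        x = nn.Tensor(RNG.normal(size=(2, 6, 8, 8)))
        out = sa(x)
        assert out.shape == x.shape

    def test_zeroed_conv_gives_half_mask(self):
        sa = SpatialAttention(np.random.default_rng(6))
        sa.conv.weight.data[...] = 0.0
        sa.conv.bias.data[...] = 0.0
        x = nn.Tensor(RNG.normal(size=(1, 3, 8, 8)))
        np.testing.assert_allclose(sa(x).data, 0.5 * x.data, atol=1e-12)


class TestFuseFeatures:
    def _proj(self):
        rng = np.random.default_rng(7)
        proj = nn.Conv2d(2, 4, 1, rng, pad=0)
        return proj

    def test_zero_local_features_additive_identity(self):
        proj = self._proj()
        proj.bias.data[...] = 0.0
        g = nn.Tensor(RNG.normal(size=(1, 4, 16, 16)))
        local = nn.Tensor(np.zeros((1, 2, 8, 8)))
        out = fuse_features(g, local, [((8, 16), (0, 8))], 4, proj)
        np.testing.assert_allclose(out.data, g.data, atol=1e-12)

    def test_sum_restricted_to_scaled_window(self):
        proj = self._proj()
        g = nn.Tensor(np.zeros((1, 4, 16, 16)))
        local = nn.Tensor(RNG.normal(size=(1, 2, 8, 8)))
        out = fuse_features(g, local, [((8, 16), (16, 24))], 4, proj).data
        # window (8..16, 16..24) at factor 4 -> rows 2..4, cols 4..6
        patch = out[:, :, 2:4, 4:6]
        assert np.abs(patch).max() > 0
        out[:, :, 2:4, 4:6] = 0.0
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_window_scaling_arithmetic(self):
        """128-wide window under x4 downsampling embeds a 32-pixel patch."""
        rng = np.random.default_rng(8)
        proj = nn.Conv2d(2, 4, 1, rng, pad=0)
        g = nn.Tensor(np.zeros((1, 4, 64, 64)))
        local = nn.Tensor(np.ones((1, 2, 128, 128)))
        out = fuse_features(g, local, [((64, 192), (64, 192))], 4, proj).data
        nonzero = np.abs(out).sum(axis=(0, 1)) > 0
        rows = np.where(nonzero.any(axis=1))[0]
        assert rows.min() == 16 and rows.max() == 47  # 32 rows

    def test_out_of_bounds_window_rejected(self):
        proj = self._proj()
        g = nn.Tensor(np.zeros((1, 4, 8, 8)))
        local = nn.Tensor(np.zeros((1, 2, 8, 8)))
        with pytest.raises(ValueError):
            fuse_features(g, local, [((120, 128), (0, 8))], 4, proj)


class TestContentRevisor:
    def _revisor(self, n=4):
        return ContentRevisor(6, n, np.random.default_rng(9))

    def test_counts_match_group_config(self):
        cr = self._revisor(4)
        m = nn.Tensor(RNG.normal(size=(2, 6, 8, 8)))
        x = nn.Tensor(RNG.uniform(-1, 1, size=(2, 3, 8, 8)))
        _, bundle = cr(m, x)
        assert bundle.content_masks.shape[1] == 3  # n-1 content masks
        assert bundle.attention_weights.shape[1] == 4

    def test_attention_sums_to_one(self):
        cr = self._revisor()
        m = nn.Tensor(RNG.normal(size=(3, 6, 8, 8)))
        x = nn.Tensor(RNG.uniform(-1, 1, size=(3, 3, 8, 8)))
        _, bundle = cr(m, x)
        np.testing.assert_allclose(bundle.attention_weights.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_background_only_attention_returns_input(self):
        cr = self._revisor()
        # bias the background logit far above the rest
        cr.fc.weight.data[...] = 0.0
        cr.fc.bias.data[...] = 0.0
        cr.fc.bias.data[-1] = 60.0
        m = nn.Tensor(RNG.normal(size=(1, 6, 8, 8)))
        x = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, 8, 8)))
        out, bundle = cr(m, x)
        np.testing.assert_allclose(bundle.attention_weights[0, -1], 1.0)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_output_bounded_by_convexity(self):
        cr = self._revisor()
        for _ in range(5):
            m = nn.Tensor(RNG.normal(0, 3, size=(1, 6, 8, 8)))
            x = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, 8, 8)))
            out, _ = cr(m, x)
            assert out.data.min() >= -1.0 and out.data.max() <= 1.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            ContentRevisor(6, 1, np.random.default_rng(0))


class TestStandardize:
    def test_moments(self):
        x = nn.Tensor(RNG.normal(3.0, 5.0, size=(2, 3, 16, 16)))
        out = standardize_channels(x).data
        np.testing.assert_allclose(out.mean(axis=(2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.var(axis=(2, 3)), 1.0, atol=1e-4)


class TestLocalGenerator:
    def test_shapes_and_bounds(self, tiny_generator, tiny_cfg):
        roi = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, tiny_cfg.roi_size,
                                                 tiny_cfg.roi_size)))
        out, feats = tiny_generator.local(roi)
        assert out.shape == (1, 3, tiny_cfg.roi_size, tiny_cfg.roi_size)
        assert np.abs(out.data).max() < 1.0
        assert feats.shape == (1, tiny_cfg.base_channels,
                               tiny_cfg.roi_size, tiny_cfg.roi_size)

    def test_encoder_shape_plan(self):
        """128-px ROI with 8 base channels encodes to 32x32x32."""
        cfg = NetworkConfig(base_channels=8, roi_size=128, global_size=256)
        gen = TranslationGenerator(cfg)
        roi = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, 128, 128)))
        h, _ = gen.local.encoder(roi)
        assert h.shape == (1, 32, 32, 32)

    def test_wrong_roi_size_rejected(self, tiny_generator):
        with pytest.raises(ValueError):
            tiny_generator.local(nn.Tensor(np.zeros((1, 3, 8, 8))))


class TestFullGenerator:
    def test_output_shapes_ranges_and_determinism(self, tiny_generator,
                                                  phantom_sample):
        from scipy import ndimage
        z = tiny_cfg_size = tiny_generator.cfg.global_size
        bmode = ndimage.zoom(phantom_sample.bmode, z / 256, order=1,
                             grid_mode=True, mode="nearest")
        mask = ndimage.zoom(phantom_sample.mask, z / 256, order=0,
                            grid_mode=True, mode="nearest")
        out1 = tiny_generator.translate(np.clip(bmode, 0, 1), mask)
        out2 = tiny_generator.translate(np.clip(bmode, 0, 1), mask)
        assert out1.global_out.shape == (1, 3, z, z)
        assert out1.roi_out.shape == (1, 3, z // 2, z // 2)
        for t in (out1.global_out, out1.roi_out):
            assert np.isfinite(t.data).all()
            assert np.abs(t.data).max() <= 1.0
        np.testing.assert_array_equal(out1.global_out.data,
                                      out2.global_out.data)

    def test_gradients_reach_every_submodule(self, tiny_cfg):
        gen = TranslationGenerator(tiny_cfg, np.random.default_rng(12))
        x = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, 32, 32)))
        roi = nn.Tensor(RNG.uniform(-1, 1, size=(1, 3, 16, 16)))
        out = gen(x, roi, [((8, 24), (8, 24))])
        ((out.global_out ** 2.0).sum() + (out.roi_out ** 2.0).sum()).backward()
        dead = [name for name, p in gen.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        # offset heads are zero-initialised yet must still receive gradient
        assert dead == []
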