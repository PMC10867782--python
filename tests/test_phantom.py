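"""Phantom generator: determinism, score bands, registration, ROI, segmentation."""

import numpy as np
import pytest
from scipy import ndimage

from tsegan.phantom import (PhantomConfig, PairedSample, blue_green_ratio,
                            extract_roi, generate_dataset,
                            generate_phantom_pair, load_manifest,
                            manifest_checksum, naive_segment, SCORE_BANDS,
                            score_from_ratio)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(image_size=32),                       # below ROI-pipeline floor
        dict(image_size=100, nodule_radius_range=(20, 60)),  # 100 < 2*60
        dict(target_score=7),
        dict(spot_density=1.5),
        dict(speckle_scale=-1.0),
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)


class TestGeneratePair:
    def test_seeded_determinism_bit_identical(self):
        cfg = PhantomConfig(seed=1, target_score=2)
        a, b = generate_phantom_pair(cfg), generate_phantom_pair(cfg)
        np.testing.assert_array_equal(a.bmode, b.bmode)
        np.testing.assert_array_equal(a.elastogram, b.elastogram)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_shapes_ranges_and_single_component(self):
        s = generate_phantom_pair(PhantomConfig(seed=5))
        assert s.bmode.shape == (256, 256)
        assert s.elastogram.shape == (256, 256, 3)
        assert 0.0 <= s.bmode.min() and s.bmode.max() <= 1.0
        assert 0.0 <= s.elastogram.min() and s.elastogram.max() <= 1.0
        assert ndimage.label(s.mask)[1] == 1

    @pytest.mark.parametrize("score", [1, 2, 3, 4, 5])
    def test_blue_fraction_in_designed_band(self, score):
        """50 seeded phantoms per score stay inside the design band."""
        lo, hi = SCORE_BANDS[score]
        for seed in range(50):
            s = generate_phantom_pair(
                PhantomConfig(seed=seed, target_score=score))
            r = blue_green_ratio(s.elastogram, s.mask)
            assert lo <= r <= hi, f"score {score} seed {seed}: ratio {r}"

    def test_extreme_scores_by_construction(self):
        s5 = generate_phantom_pair(PhantomConfig(seed=1, target_score=5))
        assert blue_green_ratio(s5.elastogram, s5.mask) >= 0.95
        s1 = generate_phantom_pair(PhantomConfig(seed=7, target_score=1))
        assert blue_green_ratio(s1.elastogram, s1.mask) <= 0.05

    def test_nodule_registration_within_two_pixels(self):
        """Blue-dominant region and B-mode nodule share a centroid."""
        for seed in range(10):
            s = generate_phantom_pair(PhantomConfig(seed=seed, target_score=4))
            e = s.elastogram
            blue = ((e[..., 2] > e[..., 0]) & (e[..., 2] > e[..., 1])
                    & (s.mask > 0))
            cm = ndimage.center_of_mass(s.mask)
            cb = ndimage.center_of_mass(blue)
            assert np.hypot(cm[0] - cb[0], cm[1] - cb[1]) <= 2.0


class TestBlueGreenRatio:
    def _nodule(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        return mask

    def test_pure_blue_and_pure_green(self):
        mask = self._nodule()
        img = np.zeros((8, 8, 3))
        img[..., 2] = 1.0
        assert blue_green_ratio(img, mask) == 1.0
        img = np.zeros((8, 8, 3))
        img[..., 1] = 1.0
        assert blue_green_ratio(img, mask) == 0.0

    def test_half_blue_counts_exactly(self):
        mask = self._nodule()
        img = np.zeros((8, 8, 3))
        img[..., 1] = 1.0
        img[2:6, 2:4, 2] = 2.0  # 8 of 16 mask pixels blue-dominant
        assert blue_green_ratio(img, mask) == 0.5

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            blue_green_ratio(np.zeros((4, 4, 3)), np.zeros((4, 4)))

    def test_score_proxy_bands(self):
        assert [score_from_ratio(r) for r in (0.0, 0.2, 0.5, 0.7, 0.99)] == \
            [1, 2, 3, 4, 5]


class TestExtractRoi:
    def test_centered_crop_window(self):
        mask = np.zeros((256, 256))
        mask[127:130, 127:130] = 1  # centroid at 128
        _, window = extract_roi(np.zeros((256, 256)), mask, 128)
        assert window == ((64, 192), (64, 192))

    def test_clamped_at_corner(self):
        mask = np.zeros((256, 256))
        mask[5, 5] = 1
        crop, window = extract_roi(np.zeros((256, 256)), mask, 128)
        assert window == ((0, 128), (0, 128))
        assert crop.shape == (128, 128)

    def test_empty_mask_falls_back_to_center(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="tsegan.phantom"):
            _, window = extract_roi(np.zeros((256, 256)),
                                    np.zeros((256, 256)), 128)
        assert window == ((64, 192), (64, 192))
        assert any("empty mask" in r.message for r in caplog.records)

    def test_output_always_roi_size(self, phantom_sample):
        crop, _ = extract_roi(phantom_sample.bmode, phantom_sample.mask, 128)
        assert crop.shape == (128, 128)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            extract_roi(np.zeros((64, 64)), np.ones((64, 64)), 128)


class TestNaiveSegment:
    def test_recovers_dark_disc(self):
        img = np.ones((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 < 100
        img[disc] = 0.1
        seg = naive_segment(img)
        assert (seg[disc] == 1).all()
        assert seg.sum() < 1.5 * disc.sum()

    def test_iou_against_true_masks(self):
        """Coarse fallback still overlaps the true nodule (IoU >= 0.3)."""
        for seed in range(20):
            s = generate_phantom_pair(PhantomConfig(seed=seed))
            seg = naive_segment(s.bmode)
            inter = ((seg > 0) & (s.mask > 0)).sum()
            union = ((seg > 0) | (s.mask > 0)).sum()
            assert inter / union >= 0.3

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            naive_segment(np.full((32, 32), 0.5))


class TestDataset:
    def test_counts_balance_and_checksum_determinism(self, tmp_path):
        cfg = PhantomConfig(image_size=96, nodule_radius_range=(10, 24),
                            seed=3)
        m1 = generate_dataset(10, cfg, tmp_path / "a")
        rows = m1.read_text().strip().split("\n")[1:]
        assert len(rows) == 10
        assert len(list((tmp_path / "a").glob("*.png"))) == 30
        scores = sorted(int(r.split("\t")[-1]) for r in rows)
        assert scores == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        m2 = generate_dataset(10, cfg, tmp_path / "b")
        assert manifest_checksum(m1) == manifest_checksum(m2)

    def test_roundtrip_and_corrupt_row_skipped(self, tmp_path, caplog):
        cfg = PhantomConfig(image_size=96, nodule_radius_range=(10, 24))
        manifest = generate_dataset(5, cfg, tmp_path)
        with open(manifest, "a") as fh:
            fh.write("broken\trow\n")
        samples = load_manifest(manifest)
        assert len(samples) == 5
        assert all(isinstance(s, PairedSample) for s in samples)
        assert all(s.bmode.shape == (96, 96) for s in samples)

    def test_scores_preserved_through_png(self, tmp_path):
        cfg = PhantomConfig(image_size=96, nodule_radius_range=(10, 24),
                            seed=9, target_score=4)
        samples = load_manifest(generate_dataset(3, cfg, tmp_path))
        for s in samples:
            lo, hi = SCORE_BANDS[4]
            assert lo <= blue_green_ratio(s.elastogram, s.mask) <= hi
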