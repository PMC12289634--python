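"""Crop detection, paired augmentation, embedding projection, dataset splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larynxseg.preprocess import (
    AugmentConfig,
    CropBox,
    SplitFractions,
    augment,
    compute_crop_bounds,
    crop,
    double_with_augmentation,
    project_embeddings,
    split_dataset,
)
from larynxseg.synthetic import Sample, render_sample, sample_scene_params

IDENTITY_AUG = AugmentConfig(crop_scale_range=(1.0, 1.0), flip_probability=0.0,
                             rotation_range_deg=0.0)
FLIP_AUG = AugmentConfig(crop_scale_range=(1.0, 1.0), flip_probability=1.0,
                         rotation_range_deg=0.0)


class TestCropBounds:
    def test_bright_rectangle_on_black(self):
        frame = np.zeros((100, 120, 3), dtype=np.float32)
        frame[10:60, 20:80] = 0.8
        box = compute_crop_bounds(frame)
        assert (box.row0, box.col0, box.height, box.width) == (10, 20, 50, 60)

    def test_all_bright_frame_is_identity(self):
        frame = np.full((40, 50, 3), 0.9, dtype=np.float32)
        box = compute_crop_bounds(frame)
        assert (box.row0, box.col0, box.height, box.width) == (0, 0, 40, 50)

    def test_largest_region_wins(self):
        frame = np.zeros((100, 100), dtype=np.float32)
        frame[5:45, 5:30] = 1.0        # 1000 px
        frame[80:85, 80:86] = 1.0      # 30 px
        box = compute_crop_bounds(frame)
        assert (box.row0, box.col0, box.height, box.width) == (5, 5, 40, 25)

    def test_all_dark_frame_is_an_error(self):
        with pytest.raises(ValueError, match="no content region"):
            compute_crop_bounds(np.zeros((20, 20, 3), dtype=np.float32))


class TestCrop:
    def test_full_frame_box_is_identity_and_idempotent(self, rng):
        frame = rng.random((30, 40, 3)).astype(np.float32)
        full = CropBox(0, 0, 30, 40)
        once = crop(frame, full)
        assert np.array_equal(once, frame)
        assert np.array_equal(crop(once, full), once)

    def test_central_block(self, rng):
        frame = rng.random((100, 100, 3)).astype(np.float32)
        out = crop(frame, CropBox(25, 25, 50, 50))
        assert np.array_equal(out, frame[25:75, 25:75])

    def test_out_of_bounds_rejected(self, rng):
        frame = rng.random((20, 20, 3)).astype(np.float32)
        with pytest.raises(ValueError):
            crop(frame, CropBox(10, 10, 15, 5))


class TestAugment:
    def test_pure_flip_is_an_involution(self, small_dataset):
        s = small_dataset[0]
        once = augment(s, FLIP_AUG, rng_seed=0)
        assert np.array_equal(once.mask, s.mask[:, ::-1])
        twice = augment(once, FLIP_AUG, rng_seed=1)
        assert np.array_equal(twice.mask, s.mask)
        np.testing.assert_allclose(twice.image, s.image, atol=1e-6)

    def test_identity_config_is_identity(self, small_dataset):
        s = small_dataset[0]
        out = augment(s, IDENTITY_AUG, rng_seed=3)
        np.testing.assert_allclose(out.image, s.image, atol=1e-6)
        assert np.array_equal(out.mask, s.mask)

    @pytest.mark.parametrize("seed", range(8))
    def test_mask_labels_never_interpolated(self, small_dataset, seed):
        s = small_dataset[seed % len(small_dataset)]
        out = augment(s, AugmentConfig(), rng_seed=seed)
        assert set(np.unique(out.mask)) <= set(np.unique(s.mask)) | {0}
        assert out.mask.dtype == np.uint8

    def test_same_seed_same_augmentation(self, small_dataset):
        s = small_dataset[1]
        a = augment(s, AugmentConfig(), rng_seed=42)
        b = augment(s, AugmentConfig(), rng_seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_geometry_stays_paired_on_binary_scene(self):
        # mask equals thresholding of the image; the relation must survive
        # the joint transform up to resampling error at the boundary
        image = np.zeros((64, 64, 3), dtype=np.float32)
        image[20:44, 12:52] = 1.0
        mask = (image[:, :, 0] > 0.5).astype(np.uint8)
        s = Sample(image=image, mask=mask)
        for seed in range(5):
            out = augment(s, AugmentConfig(), rng_seed=seed)
            rederived = (out.image[:, :, 0] > 0.5).astype(np.uint8)
            mismatch = (rederived != out.mask).mean()
            assert mismatch < 0.02, f"pairing broken at seed {seed}: {mismatch:.3f}"

    def test_doubling_emits_one_copy_per_original(self, small_dataset):
        doubled = double_with_augmentation(small_dataset[:4], AugmentConfig(), seed=0)
        assert len(doubled) == 8
        assert all(a is b for a, b in zip(doubled[:4], small_dataset))


class TestProjectEmbeddings:
    def test_identical_images_coincide_under_pca(self):
        im = np.random.default_rng(0).random((40, 40, 3))
        pts = project_embeddings([im, im, im], method="pca")
        assert pts.shape == (3, 2)
        np.testing.assert_allclose(pts, np.broadcast_to(pts[0], pts.shape), atol=1e-8)

    def test_duplicated_dataset_gives_pairwise_coincident_points(self, small_dataset):
        images = [s.image for s in small_dataset[:4]]
        pts = project_embeddings(images + images, method="pca")
        np.testing.assert_allclose(pts[:4], pts[4:], atol=1e-6)

    def test_augmented_distribution_overlaps_original(self, small_dataset):
        originals = [s.image for s in small_dataset]
        flipped = [augment(s, FLIP_AUG, rng_seed=i).image
                   for i, s in enumerate(small_dataset)]
        pts = project_embeddings(originals + flipped, method="pca")
        n = len(originals)
        a, b = pts[:n], pts[n:]
        centroid_gap = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        spread = 0.5 * (np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
                        + np.linalg.norm(b - b.mean(axis=0), axis=1).mean())
        assert centroid_gap < 2.0 * spread

    def test_tsne_path_returns_one_point_per_image(self, small_dataset):
        images = [s.image for s in small_dataset[:6]]
        pts = project_embeddings(images, method="tsne", rng_seed=0)
        assert pts.shape == (6, 2)

    def test_too_few_images_rejected(self):
        im = np.zeros((16, 16, 3))
        with pytest.raises(ValueError):
            project_embeddings([im, im], method="pca")


class TestSplitDataset:
    def test_paper_scale_split_sizes(self):
        split = split_dataset(list(range(340)), SplitFractions(0.7, 0.2, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (238, 68, 34)

    def test_ten_ids(self):
        split = split_dataset(list(range(10)), SplitFractions(0.7, 0.2, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (7, 2, 1)

    def test_deterministic_and_seed_sensitive(self):
        ids = list(range(50))
        a = split_dataset(ids, SplitFractions(), seed=5)
        b = split_dataset(ids, SplitFractions(), seed=5)
        c = split_dataset(ids, SplitFractions(), seed=6)
        assert a.train == b.train and a.val == b.val and a.test == b.test
        assert a.train != c.train

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitFractions(0.7, 0.2, 0.2)
        with pytest.raises(ValueError):
            SplitFractions(1.2, -0.1, -0.1)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(3, 400), seed=st.integers(0, 2**31 - 1))
    def test_partition_property(self, n, seed):
        ids = list(range(n))
        split = split_dataset(ids, SplitFractions(0.7, 0.2, 0.1), seed)
        groups = [set(split.train), set(split.val), set(split.test)]
        assert groups[0] | groups[1] | groups[2] == set(ids)
        assert sum(len(g) for g in groups) == n
        assert len(split.val) == int(np.floor(0.2 * n))
        assert len(split.test) == int(np.floor(0.1 * n))
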