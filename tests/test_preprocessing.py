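"""ROI cropping, resizing, normalisation and fold-splitting contracts."""

import numpy as np
import pytest

from pisunet.io import ImagePair
from pisunet.phantom import PhantomSpec, generate_phantom
from pisunet.preprocessing import (
    EmptyMaskError,
    ROIBox,
    bounding_box,
    crop_roi,
    folds_to_json,
    make_folds,
    normalize,
    preprocess_pair,
    resize_pair,
)


def _pair(image, mask):
    return ImagePair(np.asarray(image, dtype=np.float32), np.asarray(mask, dtype=np.uint8))


class TestBoundingBox:
    def test_tightest_box_from_enumerated_foreground(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 3:6] = 1  # rows {2,3,4}, cols {3,4,5}
        assert bounding_box(mask) == ROIBox(2, 3, 5, 6)

    def test_full_support_box_covers_whole_image(self):
        assert bounding_box(np.ones((4, 6))) == ROIBox(0, 0, 4, 6)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError, match="no lesion"):
            bounding_box(np.zeros((4, 4)))


class TestCropRoi:
    def test_zero_margin_returns_exact_box(self):
        pair = _pair(np.arange(64).reshape(8, 8), np.ones((8, 8)))
        out = crop_roi(pair, ROIBox(2, 3, 5, 6), margin_frac=0.0)
        assert out.shape == (3, 3)
        np.testing.assert_array_equal(out.image, pair.image[2:5, 3:6])

    def test_quarter_margin_expands_one_pixel_per_side(self):
        pair = _pair(np.zeros((10, 10)), np.ones((10, 10)))
        out = crop_roi(pair, ROIBox(2, 2, 6, 6), margin_frac=0.25)
        assert out.shape == (6, 6)  # rows/cols [1, 7)

    def test_corner_box_is_clamped_in_bounds(self):
        pair = _pair(np.zeros((8, 8)), np.ones((8, 8)))
        out = crop_roi(pair, ROIBox(0, 0, 4, 4), margin_frac=0.5)
        assert out.shape == (6, 6)  # [0, 6) after clamping at 0

    def test_zero_margin_crop_of_bounding_box_touches_all_edges(self):
        pair = generate_phantom(PhantomSpec(image_size=64, seed=21))
        out = crop_roi(pair, bounding_box(pair.mask), margin_frac=0.0)
        assert out.mask[0].any() and out.mask[-1].any()
        assert out.mask[:, 0].any() and out.mask[:, -1].any()


class TestResize:
    def test_identity_resize_preserves_values(self):
        pair = _pair(np.random.default_rng(0).random((32, 32)), np.ones((32, 32)))
        out = resize_pair(pair, 32)
        np.testing.assert_allclose(out.image, pair.image, atol=1e-6)

    def test_mask_stays_binary_after_resize(self):
        pair = generate_phantom(PhantomSpec(image_size=64, seed=2))
        out = resize_pair(pair, 48)
        assert set(np.unique(out.mask).tolist()) <= {0, 1}

    def test_nearest_neighbour_upscale_replicates_blocks(self):
        checker = np.indices((4, 4)).sum(axis=0) % 2
        pair = _pair(checker.astype(float), checker)
        out = resize_pair(pair, 32)  # then inspect 8x8 via exact replication
        expected = np.kron(checker, np.ones((8, 8), dtype=np.uint8))
        np.testing.assert_array_equal(out.mask, expected)


class TestNormalize:
    def test_minmax_formula(self):
        np.testing.assert_allclose(
            normalize(np.array([[0.0, 100.0, 200.0]]), "minmax"),
            [[0.0, 0.5, 1.0]],
        )

    @pytest.mark.parametrize("method", ["minmax", "zscore"])
    def test_constant_image_maps_to_zeros(self, method):
        out = normalize(np.full((5, 5), 3.7), method)
        np.testing.assert_array_equal(out, np.zeros((5, 5)))

    def test_zscore_standardises(self):
        rng = np.random.default_rng(1)
        out = normalize(rng.random((20, 20)) * 7 + 3, "zscore")
        assert abs(out.mean()) < 1e-6 and abs(out.std() - 1) < 1e-6


class TestFolds:
    def test_nine_patients_three_folds_sizes(self):
        patients = [f"p{i}" for i in range(9)]
        for fold in make_folds(patients, k=3, val_frac=0.2, seed=0):
            assert len(fold.test_patients) == 3
            assert len(fold.val_patients) == 2  # ceil(0.2 * 6)
            assert len(fold.train_patients) == 4

    def test_folds_partition_patients_exactly(self):
        patients = [f"p{i}" for i in range(11)]
        folds = make_folds(patients, k=3, val_frac=0.2, seed=5)
        all_test = [p for f in folds for p in f.test_patients]
        assert sorted(all_test) == sorted(patients)  # each patient tested once
        for f in folds:
            sets = [set(f.train_patients), set(f.val_patients), set(f.test_patients)]
            assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
            assert sets[0] | sets[1] | sets[2] == set(patients)

    def test_same_seed_same_split(self):
        patients = [f"p{i}" for i in range(9)]
        a = make_folds(patients, seed=42)
        b = make_folds(patients, seed=42)
        assert a == b

    def test_fewer_patients_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=3)

    def test_fold_json_round_trip(self):
        import json

        folds = make_folds([f"p{i}" for i in range(6)], k=3, seed=1)
        payload = json.loads(folds_to_json(folds))
        assert set(payload) == {"0", "1", "2"}
        assert set(payload["0"]) == {"train", "val", "test"}


def test_aspect_preserving_resize_pads_before_scaling():
    image = np.ones((4, 8), dtype=np.float32)
    mask = np.ones((4, 8), dtype=np.uint8)
    out = resize_pair(_pair(image, mask), 16, keep_aspect=True)
    assert out.shape == (16, 16)
    # original content occupies the middle band; padding rows are background
    assert out.mask[0].sum() == 0 and out.mask[-1].sum() == 0
    assert out.mask[8].sum() == 16


def test_pipeline_preserves_mask_nonemptiness():
    for seed in range(10):
        pair = generate_phantom(PhantomSpec(image_size=64, seed=seed, class_label="SCN-like"))
        out = preprocess_pair(pair, target_size=64, margin_frac=0.25)
        assert out.mask.sum() >= 1
        assert out.shape == (64, 64)
        assert set(np.unique(out.mask).tolist()) <= {0, 1}
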