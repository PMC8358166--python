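import numpy as np
import pandas as pd
import pytest

from phenorow.training_data import (
    FEATURE_COLUMNS,
    assemble_training_set,
    build_feature_table,
    extract_background_pixels,
    green_contrast,
    kmeans_plant_mask,
    neighborhood_features,
    read_table,
    write_table,
)


def _img(h, w, rgb):
    return np.broadcast_to(np.asarray(rgb, float), (h, w, 3)).copy()


class TestGreenContrast:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((1.0, 1.0, 1.0), 0.0),  # gray is zero-contrast
            ((0.0, 1.0, 0.0), 1.0 / 3.0),  # pure green hits the maximum
            ((0.3, 0.6, 0.3), 0.1),  # (−0.3 + 1.2 − 0.3) / 6
        ],
    )
    def test_pointwise_values(self, rgb, expected):
        out = green_contrast(_img(4, 5, rgb))
        assert out.shape == (4, 5)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_linearity_in_brightness(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(8, 8, 3))
        for a in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(
                green_contrast(a * img), a * green_contrast(img), atol=1e-12
            )

    def test_range_bound(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(16, 16, 3))
        gc = green_contrast(img)
        assert gc.min() >= -1 / 3 - 1e-12 and gc.max() <= 1 / 3 + 1e-12


class TestKMeansPlantPixels:
    def test_two_color_image_recovers_blob_exactly(self):
        img = _img(80, 80, (1.0, 1.0, 1.0))
        blob = np.zeros((80, 80), bool)
        blob[20:60, 30:55] = True
        img[blob] = (0.0, 1.0, 0.0)
        mask = kmeans_plant_mask(img, k=2, seed=0)
        np.testing.assert_array_equal(mask.astype(bool), blob)

    def test_k_must_be_2_or_3(self):
        img = _img(80, 80, (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="k must be"):
            kmeans_plant_mask(img, k=1)

    def test_deterministic_for_fixed_seed(self):
        from phenorow.fixtures import make_greenhouse_scene

        scene = make_greenhouse_scene(seed=3)
        m1 = kmeans_plant_mask(scene.image, k=3, seed=0)
        m2 = kmeans_plant_mask(scene.image, k=3, seed=0)
        np.testing.assert_array_equal(m1, m2)


class TestExtractBackgroundPixels:
    def test_sample_counts(self):
        crops = [_img(10, 10, (0.4, 0.3, 0.2))]
        assert len(extract_background_pixels(crops)) == 100
        crops.append(_img(5, 4, (0.6, 0.6, 0.6)))
        samples = extract_background_pixels(crops)
        assert len(samples) == 120
        assert all(s.label == 0 for s in samples)

    def test_empty_crop_list_rejected(self):
        with pytest.raises(ValueError):
            extract_background_pixels([])

    def test_crops_avoid_truth_plants(self):
        from phenorow.fixtures import background_crops, make_field_scene

        scene = make_field_scene(seed=4)
        crops = background_crops(scene, n_crops=5, seed=0)
        # windows were selected to contain zero truth plant pixels, so
        # every crop is pure background by construction of the sampler
        assert len(crops) == 5
        for crop in crops:
            assert crop.shape == (40, 60, 3)


class TestFeatureTable:
    def test_constant_image_rows_repeat_color(self):
        img = _img(6, 6, (0.2, 0.7, 0.1))
        tab = build_feature_table(img, [(2, 3), (0, 0)], label=1)
        expected = np.tile(np.tile([0.2, 0.7, 0.1], 9), (2, 1))
        np.testing.assert_allclose(tab[FEATURE_COLUMNS].to_numpy(), expected)

    def test_corner_pixel_uses_edge_replication(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(5, 5, 3))
        tab = build_feature_table(img, [(0, 0)], label=0)
        feats = tab[FEATURE_COLUMNS].to_numpy()[0].reshape(3, 3, 3)
        # replicated: all 9 neighbors drawn from the 2×2 corner block
        np.testing.assert_allclose(feats[0, 0], img[0, 0])
        np.testing.assert_allclose(feats[1, 1], img[0, 0])  # center
        np.testing.assert_allclose(feats[2, 2], img[1, 1])
        np.testing.assert_allclose(feats[0, 2], img[0, 1])

    def test_interior_pixel_matches_hand_built_patch(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(size=(3, 3, 3))
        tab = build_feature_table(img, [(1, 1)], label=1)
        expected = img.reshape(-1)  # raster order: rows, then cols, then RGB
        np.testing.assert_allclose(tab[FEATURE_COLUMNS].to_numpy()[0], expected)
        # features 12–14 are the center pixel's RGB
        np.testing.assert_allclose(
            tab[["f12", "f13", "f14"]].to_numpy()[0], img[1, 1]
        )

    def test_out_of_bounds_pixel_rejected(self):
        img = _img(4, 4, (0.5, 0.5, 0.5))
        with pytest.raises(IndexError):
            build_feature_table(img, [(4, 0)], label=0)

    def test_neighborhood_features_center_channels(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(size=(7, 9, 3))
        feats = neighborhood_features(img)
        np.testing.assert_allclose(feats[..., 12:15], img)


class TestAssembleTrainingSet:
    def _tables(self, n_plant, n_bg):
        img = _img(max(n_plant, n_bg), 3, (0.1, 0.8, 0.1))
        plant = build_feature_table(img, [(i, 0) for i in range(n_plant)], 1)
        bg = build_feature_table(img, [(i, 1) for i in range(n_bg)], 0)
        return plant, bg

    def test_positive_fraction_holds_out_at_least_one_row(self):
        plant, bg = self._tables(99, 1)
        train, val = assemble_training_set(plant, bg, holdout_frac=0.01, seed=0)
        assert len(val) == 1 and len(train) == 99

    def test_zero_holdout_gives_empty_validation(self):
        plant, bg = self._tables(10, 10)
        train, val = assemble_training_set(plant, bg, holdout_frac=0.0, seed=0)
        assert len(val) == 0 and len(train) == 20

    def test_fixed_seed_reproduces_row_order(self):
        plant, bg = self._tables(30, 30)
        t1, v1 = assemble_training_set(plant, bg, seed=7)
        t2, v2 = assemble_training_set(plant, bg, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_empty_class_rejected(self):
        plant, bg = self._tables(5, 5)
        with pytest.raises(ValueError):
            assemble_training_set(plant.iloc[:0], bg)


def test_feature_table_roundtrip_is_exact(tmp_path):
    rng = np.random.default_rng(5)
    img = rng.uniform(size=(20, 20, 3))
    tab = build_feature_table(img, [(r, c) for r in range(5) for c in range(5)], 1, "im")
    path = tmp_path / "table.csv"
    write_table(tab, path)
    back = read_table(path)
    pd.testing.assert_frame_equal(tab, back, check_exact=True)
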