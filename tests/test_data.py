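"""Synthetic scenes, Labelme conversion, mask I/O and splitting."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from cattleseg.data import (SceneRecipe, generate_color_coded_dataset,
                            generate_dataset, generate_scene, labelme_to_mask,
                            mask_to_png, png_to_mask, split_dataset)
from cattleseg.exceptions import DataError


class TestGenerator:
    def test_same_recipe_and_seed_is_bit_identical(self):
        r = SceneRecipe(canvas_size=(96, 96), seed=5)
        a, b = generate_scene(r), generate_scene(r)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_no_animals_means_empty_mask(self):
        r = SceneRecipe(canvas_size=(96, 96), n_animals=(0, 0),
                        occluder_rate=0.0, seed=1)
        assert not generate_scene(r).mask.any()

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_three_cows_make_three_mask_components(self, seed):
        r = SceneRecipe(canvas_size=(96, 96), n_animals=(3, 3), class_mix=1.0,
                        occluder_rate=0.0, seed=seed)
        mask = generate_scene(r).mask
        assert set(np.unique(mask)) == {0, 1}
        assert cc_label(mask == 1)[1] == 3

    def test_labels_stay_in_range_and_sizes_agree(self):
        for s in generate_dataset(5, SceneRecipe(canvas_size=(64, 64)), seed=2):
            assert s.image.shape[:2] == s.mask.shape
            assert set(np.unique(s.mask)) <= {0, 1, 2}

    def test_class_mix_balances_pixel_totals(self):
        """With an even cow/beef mix the two classes should contribute
        comparable pixel mass over many scenes (20% band)."""
        recipe = SceneRecipe(canvas_size=(96, 96), class_mix=0.5)
        scenes = generate_dataset(200, recipe, seed=3)
        cow = sum(int((s.mask == 1).sum()) for s in scenes)
        beef = sum(int((s.mask == 2).sum()) for s in scenes)
        assert abs(cow - beef) / max(cow, beef) < 0.20

    def test_occluders_carve_background_into_animals(self):
        heavy = SceneRecipe(canvas_size=(96, 96), n_animals=(2, 2),
                            occluder_rate=4.0, seed=23)
        none = SceneRecipe(canvas_size=(96, 96), n_animals=(2, 2),
                           occluder_rate=0.0, seed=23)
        assert generate_scene(heavy).mask.sum() <= generate_scene(none).mask.sum()

    def test_canvas_below_minimum_rejected(self):
        with pytest.raises(DataError):
            SceneRecipe(canvas_size=(32, 32))

    def test_color_coded_scenes_are_pure_rgb(self):
        scenes = generate_color_coded_dataset(3, seed=4)
        for s in scenes:
            assert set(map(tuple, np.unique(
                s.image.reshape(-1, 3), axis=0))) <= {
                    (128, 128, 128), (255, 0, 0), (0, 255, 0)}
            np.testing.assert_array_equal(
                s.mask == 1, (s.image == (255, 0, 0)).all(axis=-1))


class TestLabelme:
    def test_document_without_shapes_gives_zero_mask(self):
        mask = labelme_to_mask({"shapes": [], "imageHeight": 8, "imageWidth": 9})
        assert mask.shape == (8, 9) and not mask.any()

    def test_rectangle_covers_its_analytic_pixel_count(self):
        """A 10×20 axis-aligned rectangle with corners on half-integer
        coordinates covers exactly the 200 pixels whose centres lie
        inside."""
        doc = {"imageHeight": 32, "imageWidth": 32, "shapes": [{
            "label": "cow",
            "points": [[0.5, 0.5], [20.5, 0.5], [20.5, 10.5], [0.5, 10.5]]}]}
        mask = labelme_to_mask(doc)
        assert int((mask == 1).sum()) == 200

    def test_later_polygons_overwrite_earlier(self):
        square = [[0.5, 0.5], [10.5, 0.5], [10.5, 10.5], [0.5, 10.5]]
        doc = {"imageHeight": 16, "imageWidth": 16, "shapes": [
            {"label": "cow", "points": square},
            {"label": "beef", "points": square}]}
        mask = labelme_to_mask(doc)
        assert set(np.unique(mask)) == {0, 2}

    def test_unknown_label_is_a_data_error(self):
        doc = {"imageHeight": 8, "imageWidth": 8, "shapes": [
            {"label": "horse", "points": [[0, 0], [4, 0], [4, 4]]}]}
        with pytest.raises(DataError, match="horse"):
            labelme_to_mask(doc)

    def test_degenerate_polygon_is_skipped_with_warning(self):
        doc = {"imageHeight": 8, "imageWidth": 8, "shapes": [
            {"label": "cow", "points": [[0, 0], [4, 4]]}]}
        with pytest.warns(UserWarning, match="degenerate"):
            mask = labelme_to_mask(doc)
        assert not mask.any()

    def test_missing_size_requires_explicit_image_size(self):
        with pytest.raises(DataError):
            labelme_to_mask({"shapes": []})
        assert labelme_to_mask({"shapes": []}, image_size=(4, 4)).shape == (4, 4)


class TestMaskIO:
    def test_palette_png_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (33, 47)).astype(np.uint8)
        path = tmp_path / "m.png"
        mask_to_png(mask, path)
        np.testing.assert_array_equal(png_to_mask(path), mask)

    def test_out_of_palette_labels_rejected(self, tmp_path):
        with pytest.raises(DataError):
            mask_to_png(np.full((4, 4), 9, dtype=np.uint8), tmp_path / "m.png")


class TestSplit:
    def test_eight_to_two_on_ten_scenes(self):
        train, test = split_dataset(list(range(10)), 0.8, seed=0)
        assert len(train) == 8 and len(test) == 2
        assert sorted(train + test) == list(range(10))

    def test_same_seed_same_partition(self):
        a = split_dataset(list(range(50)), 0.8, seed=4)
        b = split_dataset(list(range(50)), 0.8, seed=4)
        assert a == b

    def test_half_up_rounding_on_odd_counts(self):
        train, test = split_dataset(list(range(781)), 0.5, seed=1)
        assert len(train) == 391 and len(test) == 390

    def test_too_few_scenes_rejected(self):
        with pytest.raises(DataError):
            split_dataset([1], 0.8, seed=0)
        with pytest.raises(DataError):
            split_dataset(list(range(10)), 1.0, seed=0)
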