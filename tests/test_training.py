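"""Schedule, training loop determinism, evaluation and ablation harness."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cattleseg.data import (SceneRecipe, generate_color_coded_dataset,
                            mask_to_png, png_to_mask, split_dataset)
from cattleseg.exceptions import ConfigurationError, DataError
from cattleseg.metrics import MetricsReport
from cattleseg.model import DESK_WIDTHS, ModelVariant, build_model
from cattleseg.training import (TABLE_COLUMNS, TrainConfig, evaluate, poly_lr,
                                run_ablation, train)


class TestPolySchedule:
    CFG = TrainConfig(epochs=1)

    def test_starts_at_the_initial_learning_rate(self):
        assert poly_lr(0, 100, self.CFG) == pytest.approx(0.01)

    def test_reaches_zero_at_the_final_iteration(self):
        assert poly_lr(100, 100, self.CFG) == 0.0

    def test_linear_special_case_halves_at_midpoint(self):
        cfg = TrainConfig(poly_power=1.0)
        assert poly_lr(50, 100, cfg) == pytest.approx(0.005)

    def test_zero_max_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            poly_lr(0, 0, self.CFG)
        with pytest.raises(ConfigurationError):
            poly_lr(5, 4, self.CFG)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(1, 500), st.floats(0.3, 2.0))
    def test_monotone_nonincreasing_and_bounded(self, max_iter, power):
        cfg = TrainConfig(lr0=0.01, poly_power=power)
        lrs = [poly_lr(i, max_iter, cfg) for i in range(max_iter + 1)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert max(lrs) <= cfg.lr0 and min(lrs) >= 0.0


class _OracleStub:
    """Predictor that returns the ground truth it was given."""

    def __init__(self, scenes):
        self._masks = {s.image.tobytes(): s.mask for s in scenes}

    def predict(self, images):
        images = np.atleast_1d(images)
        if images.ndim == 3:
            return self._masks[images.tobytes()]
        return np.stack([self._masks[im.tobytes()] for im in images])


class _ConstantStub:
    def predict(self, images):
        images = np.asarray(images)
        shape = images.shape[:3] if images.ndim == 4 else images.shape[:2]
        return np.zeros(shape, dtype=np.uint8)


class TestEvaluate:
    def test_oracle_predictor_scores_perfectly(self, tiny_scenes):
        report = evaluate(_OracleStub(tiny_scenes), tiny_scenes, num_classes=3)
        assert report.pa == report.mpa == report.miou == 1.0

    def test_constant_background_predictor(self, tiny_scenes):
        assert any((s.mask == 1).any() for s in tiny_scenes)
        report = evaluate(_ConstantStub(), tiny_scenes, num_classes=3)
        cow = report.class_names.index("cow")
        assert np.isnan(report.cpa_per_class[cow])   # no cow predictions
        assert report.iou_per_class[cow] == 0.0
        assert "cow" in report.undefined_classes

    def test_empty_test_set_is_a_data_error(self):
        with pytest.raises(DataError):
            evaluate(_ConstantStub(), [])

    def test_parity_through_saved_mask_files(self, tiny_scenes, tmp_path):
        """Scoring saved-and-reloaded prediction masks must equal direct
        evaluation: metrics are pure pixel counts."""
        from cattleseg.metrics import ConfusionMatrix, compute_report
        model = build_model(ModelVariant.from_name("m2"), widths=DESK_WIDTHS,
                            seed=0)
        direct = evaluate(model, tiny_scenes)
        cm = ConfusionMatrix(3)
        preds = model.predict(np.stack([s.image for s in tiny_scenes]))
        for i, (s, pred) in enumerate(zip(tiny_scenes, preds)):
            path = tmp_path / f"pred{i}.png"
            mask_to_png(pred, path)
            cm.add(s.mask, png_to_mask(path))
        roundtrip = compute_report(cm)
        a, b = roundtrip.to_dict(), direct.to_dict()
        assert set(a) == set(b)
        for k in a:
            if isinstance(a[k], float):
                assert a[k] == pytest.approx(b[k], nan_ok=True), k
            else:
                assert a[k] == b[k], k


@pytest.fixture(scope="module")
def surrogate_data():
    recipe = SceneRecipe(canvas_size=(64, 64), occluder_rate=0.0)
    return generate_color_coded_dataset(16, recipe, seed=17)


class TestTrainLoop:
    def test_loss_decreases_on_learnable_data(self, surrogate_data):
        model = build_model(ModelVariant.from_name("imp"), widths=DESK_WIDTHS,
                            seed=17)
        cfg = TrainConfig(input_size=64, epochs=3, seed=17)
        _, trace = train(model, surrogate_data, cfg)
        assert trace[-1]["loss"] < trace[0]["loss"]
        assert len(trace) == 3 * 4  # epochs × ceil(16/4) batches

    def test_identical_seeds_give_identical_traces(self, surrogate_data):
        losses = []
        for _ in range(2):
            model = build_model(ModelVariant.from_name("m2"),
                                widths=DESK_WIDTHS, seed=23)
            _, trace = train(model, surrogate_data,
                             TrainConfig(input_size=64, epochs=2, seed=23))
            losses.append([t["loss"] for t in trace])
        assert losses[0] == losses[1]

    def test_empty_train_set_rejected(self):
        model = build_model(ModelVariant.from_name("m2"), widths=DESK_WIDTHS)
        with pytest.raises(DataError):
            train(model, [], TrainConfig(epochs=1))

    def test_labels_beyond_num_classes_rejected(self, surrogate_data):
        model = build_model(ModelVariant.from_name("m2", num_classes=2),
                            widths=DESK_WIDTHS, seed=0)
        with pytest.raises(DataError, match="labels"):
            train(model, surrogate_data, TrainConfig(input_size=64, epochs=1))


def test_colour_separable_surrogate_reaches_high_miou():
    """On colour-coded blobs (cow pure red, beef pure green) the improved
    architecture must essentially solve the task — the "can it segment at
    all" oracle: held-out MIoU ≥ 0.95 within 20 epochs."""
    recipe = SceneRecipe(canvas_size=(96, 96), occluder_rate=0.0)
    scenes = generate_color_coded_dataset(60, recipe, seed=5)
    train_set, test_set = split_dataset(scenes, 0.8, seed=5)
    model = build_model(ModelVariant.from_name("imp"), widths=DESK_WIDTHS,
                        seed=5)
    model, _ = train(model, train_set,
                     TrainConfig(input_size=96, epochs=10, seed=5))
    report = evaluate(model, test_set)
    assert report.miou >= 0.95


class TestAblationHarness:
    def test_single_variant_gives_one_row_per_eval_set(self, surrogate_data):
        tr, te = split_dataset(surrogate_data, 0.75, seed=2)
        table = run_ablation([ModelVariant.from_name("m2")], tr,
                             {"sunny": te}, TrainConfig(input_size=64,
                                                        epochs=1, seed=2),
                             widths=DESK_WIDTHS)
        assert len(table) == 1
        assert list(table.columns[:2]) == ["model", "eval_set"]
        assert all(c in table.columns for c in TABLE_COLUMNS)

    def test_duplicate_variant_rows_are_identical(self, surrogate_data):
        tr, te = split_dataset(surrogate_data, 0.75, seed=2)
        v = ModelVariant.from_name("m2")
        table = run_ablation([v, v], tr, {"sunny": te},
                             TrainConfig(input_size=64, epochs=1, seed=2),
                             widths=DESK_WIDTHS)
        a, b = table.iloc[0], table.iloc[1]
        for c in TABLE_COLUMNS:
            assert a[c] == b[c]

    def test_failing_variant_does_not_stop_the_grid(self, surrogate_data):
        tr, te = split_dataset(surrogate_data, 0.75, seed=2)
        bad = ModelVariant.from_name("m2", num_classes=2)  # labels exceed it
        table = run_ablation([bad, ModelVariant.from_name("m2")], tr,
                             {"sunny": te},
                             TrainConfig(input_size=64, epochs=1, seed=2),
                             widths=DESK_WIDTHS)
        assert table.iloc[0]["error"] != ""
        assert np.isnan(table.iloc[0]["MIoU"])
        assert table.iloc[1]["error"] == ""
        assert not np.isnan(table.iloc[1]["MIoU"])

    def test_no_variants_rejected(self, surrogate_data):
        with pytest.raises(ConfigurationError):
            run_ablation([], surrogate_data, {}, TrainConfig(epochs=1))
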