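"""Shared fixtures.

The expensive end-to-end training run (200 synthetic 96×96 scenes,
80/20 split, desk-scale Imp network) is computed once per session and
shared by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from cattleseg.data import (SceneRecipe, generate_dataset, make_eval_sets,
                            split_dataset)
from cattleseg.model import DESK_WIDTHS, ModelVariant, build_model
from cattleseg.training import TrainConfig, evaluate, train

LEARNABILITY_SEED = 11


@pytest.fixture(scope="session")
def desk_recipe() -> SceneRecipe:
    return SceneRecipe(canvas_size=(96, 96))


@pytest.fixture(scope="session")
def tiny_scenes():
    """A handful of small scenes for fast plumbing tests."""
    return generate_dataset(6, SceneRecipe(canvas_size=(64, 64),
                                           n_animals=(1, 2)), seed=3)


@pytest.fixture(scope="session")
def learnability_run(desk_recipe):
    """Train the improved variant on 200 clear synthetic scenes.

    Returns the trained model, its loss trace, and metric reports on the
    clear ("sunny") and all-fogged ("foggy") held-out conditions.
    """
    scenes = generate_dataset(200, desk_recipe, seed=LEARNABILITY_SEED)
    train_set, test_set = split_dataset(scenes, 0.8, seed=LEARNABILITY_SEED)
    model = build_model(ModelVariant.from_name("imp"), widths=DESK_WIDTHS,
                        seed=LEARNABILITY_SEED)
    config = TrainConfig(input_size=96, epochs=12, seed=LEARNABILITY_SEED)
    model, trace = train(model, train_set, config)
    sets = make_eval_sets(test_set, seed=LEARNABILITY_SEED)
    return {
        "model": model,
        "trace": trace,
        "reports": {name: evaluate(model, subset)
                    for name, subset in sets.items()},
    }
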