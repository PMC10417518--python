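"""End-to-end replayable experiments.

``run_experiment`` wires data generation → split → fog protocol →
training → evaluation into one bundle of artifacts under an output
directory: metrics tables (CSV/JSON) for the mixed/sunny/foggy test
conditions, the loss trace, a final checkpoint, sample prediction
overlays, and a manifest listing every output with a content hash plus
the full configuration, so re-running the same config reproduces the
bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from PIL import Image

from .data import (SceneRecipe, generate_dataset, make_eval_sets, overlay_mask,
                   save_scene, split_dataset)
from .data.fog import DEFAULT_BETA_RANGE
from .exceptions import CattlesegError
from .model import (DESK_WIDTHS, ModelVariant, NetworkWidths, build_model,
                    save_checkpoint)
from .training import (TABLE_COLUMNS, TrainConfig, evaluate, save_loss_trace,
                       train)

__all__ = ["FogProtocolConfig", "ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class FogProtocolConfig:
    fraction: float = 0.5
    beta_min: float = DEFAULT_BETA_RANGE[0]
    beta_max: float = DEFAULT_BETA_RANGE[1]
    mode: str = "depth"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs, serializable to a single file."""

    recipe: SceneRecipe = field(default_factory=SceneRecipe)
    variant: str = "imp"
    train: TrainConfig = field(default_factory=TrainConfig)
    protocol: FogProtocolConfig = field(default_factory=FogProtocolConfig)
    n_scenes: int = 200
    split_ratio: float = 0.8
    widths: str = "desk"
    seed: int = 0
    output_dir: str = "experiment-out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "recipe" in d and isinstance(d["recipe"], dict):
            r = dict(d["recipe"])
            for k in ("canvas_size", "n_animals", "animal_scale"):
                if k in r:
                    r[k] = tuple(r[k])
            d["recipe"] = SceneRecipe(**r)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "protocol" in d and isinstance(d["protocol"], dict):
            d["protocol"] = FogProtocolConfig(**d["protocol"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one experiment; returns the manifest dict (also written to
    ``manifest.json``). Any stage failure marks the bundle failed with
    the stage name and diagnostic retained."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "status": "running",
                      "stages": [], "outputs": {}}
    widths = DESK_WIDTHS if config.widths == "desk" else NetworkWidths()

    def fail(stage, err):
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    try:
        scenes = generate_dataset(config.n_scenes, config.recipe, seed=config.seed)
        train_set, test_set = split_dataset(scenes, config.split_ratio,
                                            seed=config.seed)
        eval_sets = make_eval_sets(test_set,
                                   beta_range=(config.protocol.beta_min,
                                               config.protocol.beta_max),
                                   seed=config.seed, mode=config.protocol.mode,
                                   fraction=config.protocol.fraction)
        if config.protocol.fraction >= 1.0:
            eval_sets = {"foggy": eval_sets["foggy"]}
        manifest["stages"].append("data")
    except Exception as e:
        return fail("data", e)

    try:
        model = build_model(ModelVariant.from_name(config.variant),
                            widths=widths, seed=config.train.seed)
        model, trace = train(model, train_set, config.train)
        save_loss_trace(trace, out / "loss_trace.csv")
        save_checkpoint(model, out / "checkpoint.npz")
        manifest["stages"].append("train")
    except Exception as e:
        return fail("train", e)

    try:
        rows = []
        for name, subset in eval_sets.items():
            report = evaluate(model, subset)
            report.to_json(out / f"metrics_{name}.json")
            rows.append({"eval_set": name, **report.table_row()})
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        # sample prediction overlays, class colours cow=red / beef=green
        sample = eval_sets[next(iter(eval_sets))][:3]
        for i, scene in enumerate(sample):
            pred = model.predict(scene.image)
            Image.fromarray(overlay_mask(scene.image, pred)).save(
                out / f"overlay_{i}.png")
        manifest["stages"].append("evaluate")
    except Exception as e:
        return fail("evaluate", e)

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["status"] = "ok"
    manifest["metrics"] = {r["eval_set"]: {k: v for k, v in r.items()
                                           if k != "eval_set"} for r in rows}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
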