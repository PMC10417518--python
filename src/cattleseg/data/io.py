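"""Reading and writing scenes, palette masks and dataset manifests.

Masks are stored as indexed-palette PNGs with indices 0/1/2 mapped to the
display convention used throughout the package: background black, cow
red, beef green. The round trip mask → palette PNG → mask is exact.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from PIL import Image

from ..exceptions import DataError
from .scenes import LabeledScene

__all__ = ["PALETTE", "mask_to_png", "png_to_mask", "save_scene", "load_scene",
           "write_manifest", "read_manifest", "overlay_mask"]

#: index → display colour (background, cow, beef)
PALETTE = [(0, 0, 0), (255, 0, 0), (0, 255, 0)]


def mask_to_png(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise DataError("mask must be 2-D")
    if mask.max(initial=0) >= len(PALETTE):
        raise DataError(f"mask labels exceed palette size {len(PALETTE)}")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = [v for rgb in PALETTE for v in rgb]
    img.putpalette(flat + [0] * (768 - len(flat)))
    img.save(path)


def png_to_mask(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        img = img.convert("P")
    return np.asarray(img, dtype=np.uint8)


def save_scene(scene: LabeledScene, directory, stem: Optional[str] = None) -> dict:
    """Write ``<stem>.png`` (image) and ``<stem>_mask.png``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or scene.scene_id
    image_path = directory / f"{stem}.png"
    mask_path = directory / f"{stem}_mask.png"
    Image.fromarray(scene.image).save(image_path)
    mask_to_png(scene.mask, mask_path)
    return {"scene_id": scene.scene_id, "image": str(image_path),
            "mask": str(mask_path), "fogged": scene.fogged,
            "fog_strength": scene.fog_strength}


def load_scene(image_path, mask_path, scene_id: Optional[str] = None,
               fogged: bool = False, fog_strength: float = 0.0) -> LabeledScene:
    image = np.asarray(Image.open(image_path).convert("RGB"))
    mask = png_to_mask(mask_path)
    return LabeledScene(image=image, mask=mask,
                        scene_id=scene_id or Path(image_path).stem,
                        fogged=fogged, fog_strength=fog_strength)


_MANIFEST_FIELDS = ["scene_id", "image", "mask", "split", "fogged", "fog_strength"]


def write_manifest(rows: Sequence[dict], path) -> None:
    """CSV manifest: scene_id, image path, mask path, split, fog state."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in _MANIFEST_FIELDS})


def read_manifest(path) -> List[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh))


def overlay_mask(image: np.ndarray, mask: np.ndarray, alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend class colours (cow red, beef green) onto an image."""
    out = image.astype(np.float64).copy()
    for label, color in enumerate(PALETTE):
        if label == 0:
            continue
        sel = mask == label
        out[sel] = (1 - alpha) * out[sel] + alpha * np.asarray(color, dtype=np.float64)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
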