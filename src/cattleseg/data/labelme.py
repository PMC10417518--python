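"""Labelme polygon annotations → integer class masks.

Coordinates follow a pixel-centre, 0-based, row-major convention:
polygon points are (x, y) in pixel coordinates, and a pixel belongs to a
polygon when its centre falls inside. Shapes are rasterized in file
order, so later polygons overwrite earlier ones; unlabelled pixels stay
background (0).
"""

from __future__ import annotations

import json
import warnings
from typing import Dict, Optional, Tuple

import numpy as np
from skimage.draw import polygon as _fill_polygon

from ..exceptions import DataError
from .scenes import CLASS_LABELS

__all__ = ["labelme_to_mask", "load_labelme"]


def load_labelme(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def labelme_to_mask(annotation: dict,
                    class_map: Optional[Dict[str, int]] = None,
                    image_size: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Rasterize a Labelme JSON document into a label mask.

    ``class_map`` maps shape labels to class indices (default: the
    background/cow/beef convention). Unknown labels raise
    :class:`DataError`; polygons with fewer than three vertices are
    skipped with a warning.
    """
    class_map = class_map or CLASS_LABELS
    if image_size is None:
        try:
            image_size = (int(annotation["imageHeight"]),
                          int(annotation["imageWidth"]))
        except KeyError as e:
            raise DataError("annotation lacks imageHeight/imageWidth and no "
                            "image_size was given") from e
    mask = np.zeros(image_size, dtype=np.uint8)
    for shape in annotation.get("shapes", []):
        label = shape.get("label")
        if label not in class_map:
            raise DataError(f"unknown annotation label {label!r}; "
                            f"known labels: {sorted(class_map)}")
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(f"skipping degenerate polygon for label {label!r} "
                          f"({len(pts)} vertices)", stacklevel=2)
            continue
        rr, cc = _fill_polygon(pts[:, 1], pts[:, 0], shape=image_size)
        mask[rr, cc] = class_map[label]
    return mask
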