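"""Labeled scenes and the procedural multi-animal scene generator.

The generator emulates the structure of barn/paddock imagery used for
cattle segmentation: a textured ground background, one or more animals of
two visually distinct classes — "cow" (light coat with high-contrast dark
patches, label 1) and "beef" (uniform dark warm-brown coat, label 2) —
drawn as ellipse composites (body plus attached head) in random poses,
optionally occluded by railing bars which revert the mask to background
where they cover an animal. Every scene is produced from a
:class:`SceneRecipe` plus its seed, and identical recipe + seed give a
bit-identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from ..exceptions import DataError

__all__ = ["LabeledScene", "SceneRecipe", "generate_scene", "generate_dataset",
           "CLASS_LABELS"]

CLASS_LABELS = {"background": 0, "cow": 1, "beef": 2}


@dataclass
class LabeledScene:
    """An RGB image with its per-pixel class mask and metadata."""

    image: np.ndarray          # H×W×3 uint8
    mask: np.ndarray           # H×W uint8, labels in {0, 1, 2}
    scene_id: str
    fogged: bool = False
    fog_strength: float = 0.0

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise DataError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} sizes differ")
        if self.fog_strength < 0:
            raise DataError("fog_strength must be non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SceneRecipe:
    """Parameters of one synthetic scene (deterministic given ``seed``).

    ``n_animals`` is an inclusive (lo, hi) range; ``class_mix`` is the
    probability that an animal is a cow rather than a beef animal;
    ``occluder_rate`` is the expected number of railing bars per scene
    (Poisson). Animal size is relative to the short canvas side.
    """

    canvas_size: Tuple[int, int] = (480, 480)
    n_animals: Tuple[int, int] = (1, 4)
    class_mix: float = 0.5
    occluder_rate: float = 1.0
    animal_scale: Tuple[float, float] = (0.10, 0.16)
    cow_patch_scale: float = 6.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.canvas_size
        if h < 64 or w < 64:
            raise DataError("canvas must be at least 64×64")
        if not 0.0 <= self.class_mix <= 1.0:
            raise DataError("class_mix must be in [0, 1]")
        if self.n_animals[0] < 0 or self.n_animals[1] < self.n_animals[0]:
            raise DataError("n_animals must be a non-decreasing, non-negative range")


def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Grass/dirt ground: low-frequency colour field plus fine speckle."""
    base = np.array([96.0, 118.0, 72.0])  # muted green-brown
    low = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 12.0)
    low = low / (np.abs(low).max() + 1e-9)
    speckle = rng.normal(0.0, 6.0, (h, w))
    img = base[None, None, :] + 28.0 * low[:, :, None] + speckle[:, :, None]
    img += rng.normal(0.0, 3.0, (h, w, 3))
    return img


def _animal_footprint(h, w, rng, scale_range):
    """Body + head ellipse pixel coordinates, or None if out of canvas."""
    s = min(h, w)
    a = rng.uniform(*scale_range) * s          # body semi-major
    b = a * rng.uniform(0.45, 0.65)            # body semi-minor
    theta = rng.uniform(0.0, np.pi)
    cy = rng.uniform(a, h - a)
    cx = rng.uniform(a, w - a)
    body = ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
    # head: smaller ellipse overlapping one end of the major axis
    hy = cy + 0.88 * a * np.cos(theta)
    hx = cx + 0.88 * a * np.sin(theta)
    head = ellipse(hy, hx, 0.40 * a, 0.32 * a, shape=(h, w), rotation=theta)
    return body, head, (cy, cx, a)


def _paint_cow(img, mask_sel, h, w, rng, patch_scale):
    """Light coat with high-contrast dark patches."""
    coat = np.array([228.0, 226.0, 222.0])
    patches = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=patch_scale)
    dark = patches > 0.35 * patches.std() + patches.mean()
    colors = np.where(dark[:, :, None], np.array([38.0, 34.0, 30.0]), coat)
    img[mask_sel] = colors[mask_sel] + rng.normal(0.0, 4.0, (h, w, 3))[mask_sel]


def _paint_beef(img, mask_sel, h, w, rng):
    """Uniform dark warm-brown coat."""
    coat = np.array([122.0, 62.0, 36.0]) + rng.normal(0.0, 6.0, 3)
    img[mask_sel] = coat[None, :] + rng.normal(0.0, 4.0, (h, w, 3))[mask_sel]


def generate_scene(recipe: SceneRecipe) -> LabeledScene:
    """Render one synthetic scene with its exact ground-truth mask.

    Animals are placed by rejection sampling so their footprints do not
    touch (keeps per-animal mask components separable); railing occluders
    are drawn last and set occluded pixels back to background in the mask.
    """
    h, w = recipe.canvas_size
    rng = np.random.default_rng(recipe.seed)
    img = _background(h, w, rng)
    mask = np.zeros((h, w), dtype=np.uint8)

    n_animals = int(rng.integers(recipe.n_animals[0], recipe.n_animals[1] + 1))
    placed: List[Tuple[float, float, float]] = []
    painted = 0
    attempts = 0
    while painted < n_animals and attempts < 300:
        attempts += 1
        body, head, (cy, cx, a) = _animal_footprint(h, w, rng, recipe.animal_scale)
        # enforce a clearance between animal centres
        if any(np.hypot(cy - py, cx - px) < 1.45 * (a + pa) + 2
               for py, px, pa in placed):
            continue
        sel = np.zeros((h, w), dtype=bool)
        sel[body] = True
        sel[head] = True
        label = 1 if rng.random() < recipe.class_mix else 2
        if label == 1:
            _paint_cow(img, sel, h, w, rng, recipe.cow_patch_scale)
        else:
            _paint_beef(img, sel, h, w, rng)
        mask[sel] = label
        placed.append((cy, cx, a))
        painted += 1

    n_rails = int(rng.poisson(recipe.occluder_rate))
    rail_color = np.array([150.0, 148.0, 144.0])
    for _ in range(n_rails):
        thickness = int(rng.integers(2, max(3, h // 32)))
        if rng.random() < 0.5:   # horizontal bar
            y0 = int(rng.integers(0, h - thickness))
            band = (slice(y0, y0 + thickness), slice(None))
        else:                    # vertical post
            x0 = int(rng.integers(0, w - thickness))
            band = (slice(None), slice(x0, x0 + thickness))
        img[band] = rail_color + rng.normal(0.0, 3.0, img[band].shape)
        mask[band] = 0

    image = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledScene(image=image, mask=mask,
                        scene_id=f"scene-{recipe.seed:06d}")


def generate_dataset(n_scenes: int, recipe: Optional[SceneRecipe] = None,
                     seed: int = 0) -> List[LabeledScene]:
    """Generate ``n_scenes`` scenes, one derived seed per scene."""
    recipe = recipe or SceneRecipe()
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(n_scenes) % (2**31 - 1)
    return [generate_scene(replace(recipe, seed=int(s))) for s in seeds]


def generate_color_coded_scene(recipe: SceneRecipe) -> LabeledScene:
    """A linearly colour-separable variant of :func:`generate_scene`.

    Pure red blobs are cows (label 1) and pure green blobs are beef
    (label 2) on a flat mid-grey background — a sanity dataset where
    class identity is decidable from a single pixel's colour, used to
    check that a segmentation architecture can learn at all.
    """
    h, w = recipe.canvas_size
    rng = np.random.default_rng(recipe.seed)
    img = np.full((h, w, 3), 128, dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.uint8)
    n_animals = int(rng.integers(recipe.n_animals[0], recipe.n_animals[1] + 1))
    placed: List[Tuple[float, float, float]] = []
    painted = 0
    attempts = 0
    while painted < n_animals and attempts < 300:
        attempts += 1
        body, head, (cy, cx, a) = _animal_footprint(h, w, rng, recipe.animal_scale)
        if any(np.hypot(cy - py, cx - px) < 1.45 * (a + pa) + 2
               for py, px, pa in placed):
            continue
        sel = np.zeros((h, w), dtype=bool)
        sel[body] = True
        sel[head] = True
        label = 1 if rng.random() < recipe.class_mix else 2
        img[sel] = (255.0, 0.0, 0.0) if label == 1 else (0.0, 255.0, 0.0)
        mask[sel] = label
        placed.append((cy, cx, a))
        painted += 1
    return LabeledScene(image=img.astype(np.uint8), mask=mask,
                        scene_id=f"colorcoded-{recipe.seed:06d}")


def generate_color_coded_dataset(n_scenes: int,
                                 recipe: Optional[SceneRecipe] = None,
                                 seed: int = 0) -> List[LabeledScene]:
    recipe = recipe or SceneRecipe(canvas_size=(96, 96), occluder_rate=0.0)
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(n_scenes) % (2**31 - 1)
    return [generate_color_coded_scene(replace(recipe, seed=int(s)))
            for s in seeds]
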