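"""Synthetic fog degradation and the fogged-test-set protocol.

Fog is composited with the atmospheric-scattering model

    I(p) = J(p)·t(p) + A·(1 − t(p)),      t(p) = exp(−β·d(p)),

where J is the clear image, A the airlight colour, β the fog strength and
d a smooth pseudo-depth field (scenes are photographed roughly
horizontally, so depth increases towards the top of the frame; a seeded
low-frequency field adds spatial variation). A ``uniform`` mode with a
constant depth of 1 is available as a simpler fallback. The class mask is
never altered by fogging.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ..exceptions import DataError
from .scenes import LabeledScene

__all__ = ["pseudo_depth", "apply_fog", "fog_test_protocol", "make_eval_sets",
           "DEFAULT_AIRLIGHT", "DEFAULT_BETA_RANGE"]

DEFAULT_AIRLIGHT: Tuple[int, int, int] = (235, 235, 235)
#: Fog strengths drawn for the degraded test images: visible haze up to
#: near-whiteout at the top of the frame.
DEFAULT_BETA_RANGE: Tuple[float, float] = (0.6, 1.6)


def pseudo_depth(shape: Tuple[int, int], seed: int = 0) -> np.ndarray:
    """Smooth positive pseudo-depth: vertical gradient + low-freq noise."""
    h, w = shape
    rows = np.linspace(1.0, 0.0, h)[:, None]          # far at the top
    grad = 0.35 + 1.15 * (1.0 - rows)
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=max(h, w) / 8.0)
    noise = noise / (np.abs(noise).max() + 1e-9)
    depth = grad + 0.25 * noise
    return np.maximum(np.broadcast_to(depth, shape).copy()
                      if depth.shape != shape else depth, 0.05)


def apply_fog(scene: LabeledScene, strength: float,
              airlight: Sequence[int] = DEFAULT_AIRLIGHT,
              seed: int = 0, mode: str = "depth") -> LabeledScene:
    """Composite fog of strength β onto a scene; the mask is unchanged.

    β = 0 returns a pixel-identical image; β → ∞ drives every pixel to
    the airlight colour.
    """
    if strength < 0:
        raise DataError("fog strength must be non-negative")
    if mode == "depth":
        d = pseudo_depth(scene.mask.shape, seed=seed)
    elif mode == "uniform":
        d = np.ones(scene.mask.shape)
    else:
        raise DataError(f"unknown fog mode {mode!r}")
    t = np.exp(-strength * d)[:, :, None]
    a = np.asarray(airlight, dtype=np.float64)[None, None, :]
    img = scene.image.astype(np.float64) * t + a * (1.0 - t)
    return LabeledScene(image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
                        mask=scene.mask.copy(),
                        scene_id=scene.scene_id,
                        fogged=strength > 0,
                        fog_strength=float(strength))


def fog_test_protocol(test_set: Sequence[LabeledScene], fraction: float = 0.5,
                      beta_range: Tuple[float, float] = DEFAULT_BETA_RANGE,
                      seed: int = 0, supplement: bool = False,
                      mode: str = "depth") -> List[LabeledScene]:
    """Fog a deterministic random half (by default) of a test set.

    ``round(fraction·N)`` scenes are selected under ``seed`` and replaced
    by fogged copies with β drawn uniformly from ``beta_range``; with
    ``supplement=True`` the fogged copies are appended instead, keeping
    the clear originals.
    """
    scenes = list(test_set)
    if not scenes:
        raise DataError("fog protocol needs a non-empty test set")
    if not 0.0 <= fraction <= 1.0:
        raise DataError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fog = int(np.floor(fraction * len(scenes) + 0.5))
    chosen = set(rng.choice(len(scenes), size=n_fog, replace=False)) if n_fog else set()
    out: List[LabeledScene] = []
    for i, s in enumerate(scenes):
        if i in chosen:
            beta = float(rng.uniform(*beta_range))
            fogged = apply_fog(s, beta, seed=int(rng.integers(2**31 - 1)), mode=mode)
            if supplement:
                out.append(s)
            out.append(fogged)
        else:
            out.append(s)
    return out


def make_eval_sets(test_set: Sequence[LabeledScene],
                   beta_range: Tuple[float, float] = DEFAULT_BETA_RANGE,
                   seed: int = 0, mode: str = "depth",
                   fraction: float = 0.5) -> Dict[str, List[LabeledScene]]:
    """The three evaluation conditions: mixed (fraction fogged), all-clear
    ("sunny") and all-fogged ("foggy")."""
    return {
        "original": fog_test_protocol(test_set, fraction=fraction,
                                      beta_range=beta_range, seed=seed, mode=mode),
        "sunny": list(test_set),
        "foggy": fog_test_protocol(test_set, fraction=1.0,
                                   beta_range=beta_range, seed=seed, mode=mode),
    }
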