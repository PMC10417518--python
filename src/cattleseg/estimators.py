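"""scikit-learn style estimator facade.

``ImpDeepLabSegmenter`` wraps model construction, the seeded training
loop and evaluation behind the fit/predict/score protocol, so the
segmenter composes with sklearn pipelines and model selection. ``X`` is
a batch of RGB images ``(n, H, W, 3)`` (uint8 or floats in [0, 1]) and
``y`` the integer class masks ``(n, H, W)``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .data.scenes import LabeledScene
from .exceptions import DataError
from .metrics import ConfusionMatrix, miou as _miou
from .model import DESK_WIDTHS, ModelVariant, NetworkWidths, build_model
from .training import TrainConfig, evaluate, train

__all__ = ["ImpDeepLabSegmenter"]

_WIDTH_PRESETS = {"full": NetworkWidths(), "desk": DESK_WIDTHS}


class ImpDeepLabSegmenter(BaseEstimator):
    """Per-pixel cattle/background classifier (improved DeepLabV3+).

    Parameters
    ----------
    variant:
        ``"imp"`` (layerwise decoder + SE), ``"m2u"`` (layerwise decoder)
        or ``"m2"`` (single-fusion decoder).
    widths:
        ``"full"`` for the standard channel widths (ASPP/decoder 256),
        ``"desk"`` for the narrow CPU-scale profile, or a
        :class:`~cattleseg.model.NetworkWidths` instance.
    num_classes, epochs, batch_size, lr0, momentum, poly_power,
    augment_hflip, seed:
        Forwarded to the training configuration; the poly learning-rate
        schedule decays from ``lr0`` to 0 over all iterations.

    Attributes
    ----------
    model_ : SegmentationNetwork
        The trained network.
    loss_trace_ : list of dict
        Per-iteration loss and learning rate.
    n_iter_ : int
        Number of optimisation steps performed.
    """

    def __init__(self, variant: str = "imp", widths="desk", num_classes: int = 3,
                 epochs: int = 12, batch_size: int = 4, lr0: float = 0.01,
                 momentum: float = 0.9, poly_power: float = 0.9,
                 augment_hflip: bool = True, seed: int = 0):
        self.variant = variant
        self.widths = widths
        self.num_classes = num_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.momentum = momentum
        self.poly_power = poly_power
        self.augment_hflip = augment_hflip
        self.seed = seed

    # -- internals -----------------------------------------------------------
    def _widths(self) -> NetworkWidths:
        if isinstance(self.widths, NetworkWidths):
            return self.widths
        try:
            return _WIDTH_PRESETS[self.widths]
        except KeyError:
            raise ValueError(f"widths must be 'full', 'desk' or NetworkWidths, "
                             f"got {self.widths!r}") from None

    @staticmethod
    def _as_scenes(X, y) -> Sequence[LabeledScene]:
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise DataError(f"X must be (n, H, W, 3), got {X.shape}")
        if y.shape != X.shape[:3]:
            raise DataError(f"y must be (n, H, W) matching X, got {y.shape}")
        if X.dtype != np.uint8:
            X = np.clip(np.asarray(X, dtype=np.float64) * 255.0, 0, 255).astype(np.uint8)
        return [LabeledScene(image=xi, mask=yi.astype(np.uint8),
                             scene_id=f"fit-{i:05d}")
                for i, (xi, yi) in enumerate(zip(X, y))]

    # -- sklearn protocol ----------------------------------------------------
    def fit(self, X, y):
        scenes = self._as_scenes(X, y)
        config = TrainConfig(
            input_size=scenes[0].shape[0], batch_size=self.batch_size,
            lr0=self.lr0, momentum=self.momentum, epochs=self.epochs,
            poly_power=self.poly_power, seed=self.seed,
            augment_hflip=self.augment_hflip)
        model = build_model(ModelVariant.from_name(self.variant, self.num_classes),
                            widths=self._widths(), seed=self.seed)
        model, trace = train(model, scenes, config)
        self.model_ = model
        self.loss_trace_ = trace
        self.n_iter_ = len(trace)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X)
        if X.dtype != np.uint8:
            X = np.clip(np.asarray(X, dtype=np.float64) * 255.0, 0, 255).astype(np.uint8)
        return self.model_.predict(X, batch_size=self.batch_size)

    def score(self, X, y) -> float:
        """Mean intersection over union on (X, y)."""
        self._check_fitted()
        cm = ConfusionMatrix(self.num_classes)
        cm.add(np.asarray(y), self.predict(X))
        return _miou(cm)

    def evaluate(self, scenes: Sequence[LabeledScene], **kw):
        """Full metrics report (PA/CPA/MPA/IoU/MIoU) on labelled scenes."""
        self._check_fitted()
        return evaluate(self.model_, scenes, **kw)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DataError("this segmenter is not fitted yet; call fit first")
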