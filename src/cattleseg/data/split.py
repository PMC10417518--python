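"""Deterministic train/test splitting (per-image granularity)."""

from __future__ import annotations

from typing import List, Sequence, Tuple, TypeVar

import numpy as np

from ..exceptions import DataError

__all__ = ["split_dataset"]

T = TypeVar("T")


def split_dataset(scenes: Sequence[T], ratio: float = 0.8,
                  seed: int = 0) -> Tuple[List[T], List[T]]:
    """Shuffle under ``seed`` and split; |train| = round(ratio·N).

    Rounding is half-up, the partition is disjoint and exhaustive, and
    identical seeds give identical partitions.
    """
    if not 0.0 < ratio < 1.0:
        raise DataError("split ratio must lie strictly between 0 and 1")
    scenes = list(scenes)
    n = len(scenes)
    if n < 2:
        raise DataError("need at least 2 scenes to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)   # both sides non-empty
    train = [scenes[i] for i in order[:n_train]]
    test = [scenes[i] for i in order[n_train:]]
    return train, test
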