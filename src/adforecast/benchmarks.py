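"""Reference forecasters: the uniform and the patient-historical benchmark.

Both emit the same 5-category pmf objects as the fitted model, so they plug
directly into the scoring machinery.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import K_CATEGORIES


def uniform_forecast() -> np.ndarray:
    """The ignorance benchmark: probability one-fifth for each score."""
    return np.full(K_CATEGORIES, 1.0 / K_CATEGORIES)


def historical_forecast(history: Sequence[int]) -> np.ndarray:
    """Per-category relative frequency in the patient's own past scores.

    Zero-frequency categories get probability exactly 0 (no smoothing); an
    empty history falls back to the uniform forecast.
    """
    history = np.asarray(list(history), dtype=float)
    history = history[~np.isnan(history)]
    if history.size == 0:
        return uniform_forecast()
    counts = np.bincount(history.astype(int), minlength=K_CATEGORIES).astype(float)
    return counts / counts.sum()
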