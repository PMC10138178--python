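"""Mixture-of-experts seasonal–trend decomposition.

The trend of a sequence is a softmax-weighted combination of moving averages
at several odd window lengths; the seasonal part is the residual, so
``seasonal + trend == input`` holds exactly by construction.  Sequence ends
are padded by edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = ["DecompResult", "MoeDecompConfig", "moving_average",
           "moving_average_matrix", "moe_decomp"]


@dataclass
class DecompResult:
    seasonal: np.ndarray
    trend: np.ndarray
    weights: np.ndarray | None = None  # kernel-mixing weights (sum to 1)


@dataclass(frozen=True)
class MoeDecompConfig:
    """Kernel sizes (odd, in days) and how mixing logits are produced.

    ``per_step=False`` uses one fixed logit per kernel (``logits``);
    ``per_step=True`` is the learnable per-time-step mode used inside the
    forecaster, where a linear map of the input produces the logits.
    """

    kernel_sizes: tuple[int, ...] = (5, 9, 13)
    per_step: bool = False
    logits: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.kernel_sizes) == 0:
            raise ValueError("kernel_sizes must be nonempty")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel size {k} must be odd and >= 1")
        if self.logits is not None and len(self.logits) != len(self.kernel_sizes):
            raise ValueError("one logit per kernel required")


def moving_average(x: np.ndarray, kernel: int) -> np.ndarray:
    """Centred moving average with edge-replicated padding, same length as x.

    Works on 1-D sequences or (length, channels) arrays (averaged along axis 0).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size {kernel} must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    if kernel == 1:
        return x.copy()
    return uniform_filter1d(x, size=kernel, axis=0, mode="nearest")


def moving_average_matrix(length: int, kernel: int) -> np.ndarray:
    """The (length, length) linear operator equivalent to ``moving_average``.

    Used by the forecaster so the filter participates in autodiff as a plain
    matrix product.  Edge replication shows up as accumulated weight on the
    first/last columns.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size {kernel} must be odd and >= 1")
    half = kernel // 2
    a = np.zeros((length, length))
    for t in range(length):
        idx = np.clip(np.arange(t - half, t + half + 1), 0, length - 1)
        np.add.at(a[t], idx, 1.0 / kernel)
    return a


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def moe_decomp(x: np.ndarray, config: MoeDecompConfig = MoeDecompConfig()) -> DecompResult:
    """Decompose ``x`` into (seasonal, trend) with mixing weights summing to 1.

    With fixed logits (default: all zero, i.e. equal weights) the trend is the
    convex combination of the per-kernel moving averages; the seasonal part is
    the exact residual.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("input sequence is empty")
    trends = np.stack([moving_average(x, k) for k in config.kernel_sizes], axis=0)
    logits = np.zeros(len(config.kernel_sizes)) if config.logits is None \
        else np.asarray(config.logits, dtype=float)
    w = _softmax(logits)
    trend = np.tensordot(w, trends, axes=(0, 0))
    return DecompResult(seasonal=x - trend, trend=trend, weights=w)
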