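"""Kernel dilation of sparse time-series ratings before model fitting.

Continuous affect annotations are strongly autocorrelated, so a rating
observed at time t is informative about neighboring seconds. Dilation
exploits this: each *training*-observed rating is spread to the surrounding
time points inside a boxcar window, and a point covered by several windows
takes the unweighted mean of the contributing ratings (a boxcar weights all
contributions equally). The result is a denser training matrix.

Leakage semantics are strict: only cells flagged in ``train_mask``
contribute, originally observed training values are never altered, and held
out (test) values cannot influence the output -- dilation happens after
masking, on the training side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RatingsMatrix

__all__ = ["DilationKernel", "dilate"]


@dataclass
class DilationKernel:
    """A boxcar smoothing window specified in seconds.

    ``width_samples`` is derived per matrix: ``round(width_s / interval)``,
    at least 1, and forced odd (rounding up) so the window is symmetric
    about the observed sample.
    """

    width_s: float
    shape: str = "boxcar"

    def __post_init__(self) -> None:
        if self.shape != "boxcar":
            raise ValueError(f"unsupported kernel shape {self.shape!r}")
        if not self.width_s > 0:
            raise ValueError("kernel width must be positive")

    def width_samples(self, sample_interval_s: float) -> int:
        w = max(1, round(self.width_s / sample_interval_s))
        if w % 2 == 0:
            w += 1
        return w


def dilate(
    matrix: RatingsMatrix, train_mask: np.ndarray, kernel: DilationKernel
) -> RatingsMatrix:
    """Spread each training-observed rating across its boxcar window.

    Returns a new matrix in which, per user, every cell within
    ``±(width_samples // 2)`` time points of a train-observed rating holds
    the unweighted mean of the train-observed ratings whose windows cover
    it. Train-observed cells keep their original values; cells outside any
    window stay missing. Windows truncate at the series edges.
    """
    if not matrix.has_time_axis:
        raise ValueError("dilation requires a time axis")
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != matrix.values.shape:
        raise ValueError("train_mask shape does not match matrix")
    width = kernel.width_samples(matrix.sample_interval_s)
    n_items = matrix.n_items
    if width > n_items:
        raise ValueError(
            f"kernel width {width} samples exceeds series length {n_items}"
        )
    half = width // 2
    out = np.full_like(matrix.values, np.nan)
    box = np.ones(width)
    for u in range(matrix.n_users):
        obs = train_mask[u]
        vals = np.where(obs, matrix.values[u], 0.0)
        # windowed sums of observed values and of observed-counts; their
        # ratio is the equal-weight mean over covering windows
        total = np.convolve(vals, box, mode="same")
        count = np.convolve(obs.astype(float), box, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            filled = total / count
        row = np.where(count > 0, filled, np.nan)
        row[obs] = matrix.values[u, obs]  # never alter observed training values
        out[u] = row
    return matrix.with_values(out)
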