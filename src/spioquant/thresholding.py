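"""Global threshold selection and binarization.

Two threshold rules are provided:

* **Otsu** — exhaustive search over all candidate thresholds T for the one
  minimizing the intra-class variance ``w0(T)·s0²(T) + w1(T)·s1²(T)``, where
  class 0 holds gray levels g < T and class 1 holds g >= T. This is the
  classical global method for separating electron-dense particles from a
  lighter background.
* **First minimum** — the first valley of the (smoothed) histogram scanning
  upward from the darkest occupied level; a common manual alternative when
  the particle mode is well separated from the background mode.

Binarization follows the rule: h(i,j) = 255 (background, white) where
f(i,j) >= T and h(i,j) = 0 (particle, "red") where f(i,j) < T. Foreground is
thus the 0-valued, below-threshold class throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .image_model import GrayImage, IntensityHistogram

FOREGROUND = 0
BACKGROUND = 255


@dataclass(frozen=True)
class ThresholdResult:
    """A chosen global threshold with method provenance.

    ``candidates``/``objective_curve`` hold the admissible Otsu candidates
    and their intra-class variances; ``smoothed_counts`` holds the smoothed
    histogram for the first-minimum rule. ``fallback`` is True when the
    first-minimum rule found no valley and deferred to Otsu.
    """

    threshold: int
    method: str
    candidates: Optional[np.ndarray] = None
    objective_curve: Optional[np.ndarray] = None
    smoothed_counts: Optional[np.ndarray] = None
    fallback: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValidationError(f"threshold {self.threshold} outside [0, 255]")


@dataclass(frozen=True)
class SegmentedImage:
    """Binarized raster over {0, 255} aligned with its source image."""

    labels: np.ndarray
    threshold_used: ThresholdResult
    pixel_size_nm: float
    foreground_value: int = FOREGROUND
    background_value: int = BACKGROUND

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.isin(lab, (FOREGROUND, BACKGROUND)).all():
            raise ValidationError("segmentation labels must be 0 or 255")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def foreground_mask(self) -> np.ndarray:
        return self.labels == FOREGROUND

    @property
    def foreground_count(self) -> int:
        return int(self.foreground_mask.sum())


def _check_nondegenerate(hist: IntensityHistogram) -> None:
    if len(hist.occupied_levels) < 2:
        raise ValidationError("degenerate histogram: no threshold separates classes")


def otsu_threshold(hist: IntensityHistogram) -> ThresholdResult:
    """Exhaustive Otsu threshold from a 256-bin histogram.

    Scans T in [1, 255]; candidates that leave either class empty are
    inadmissible. Returns the smallest T attaining the minimal intra-class
    variance.
    """
    _check_nondegenerate(hist)
    counts = hist.counts.astype(float)
    levels = np.arange(256, dtype=float)
    n = counts.sum()

    c0 = np.cumsum(counts)            # pixels with g < T at index T-1
    s0 = np.cumsum(counts * levels)
    q0 = np.cumsum(counts * levels**2)

    ts = np.arange(1, 256)
    n0 = c0[ts - 1]
    n1 = n - n0
    admissible = (n0 > 0) & (n1 > 0)
    ts = ts[admissible]
    n0 = n0[admissible]
    n1 = n1[admissible]
    sum0 = s0[ts - 1]
    sum1 = s0[255] - sum0
    sq0 = q0[ts - 1]
    sq1 = q0[255] - sq0

    var0 = sq0 / n0 - (sum0 / n0) ** 2
    var1 = sq1 / n1 - (sum1 / n1) ** 2
    objective = (n0 * var0 + n1 * var1) / n
    # numerical floor: variance of a single-level class can come out ~-1e-12
    objective = np.maximum(objective, 0.0)

    best = int(ts[int(np.argmin(objective))])  # argmin takes the smallest T on ties
    return ThresholdResult(
        threshold=best,
        method="otsu",
        candidates=ts,
        objective_curve=objective,
    )


def _smooth_counts(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge bins average over the partial window."""
    kernel = np.ones(window)
    sums = np.convolve(counts.astype(float), kernel, mode="same")
    norm = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return sums / norm


def first_minimum_threshold(
    hist: IntensityHistogram, smooth_window: int = 5
) -> ThresholdResult:
    """Threshold at the first valley of the smoothed histogram.

    The histogram is smoothed with a centered moving average of width
    ``smooth_window`` (odd), then scanned upward from the first occupied
    gray level for the smallest g with ``smoothed(g) < smoothed(g-1)`` and
    ``smoothed(g) <= smoothed(g+1)``. If no interior valley exists the Otsu
    threshold is returned with ``fallback=True``.
    """
    _check_nondegenerate(hist)
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError(
            f"smooth_window must be an odd positive integer, got {smooth_window}"
        )
    smoothed = _smooth_counts(hist.counts, smooth_window)
    first_occupied = int(hist.occupied_levels[0])
    last_occupied = int(hist.occupied_levels[-1])
    # the valley must lie inside the occupied support: past the last
    # occupied bin the smoothed curve trivially decays to zero
    for g in range(max(first_occupied, 1), min(last_occupied, 255)):
        if smoothed[g] < smoothed[g - 1] and smoothed[g] <= smoothed[g + 1]:
            return ThresholdResult(
                threshold=g, method="first_minimum", smoothed_counts=smoothed
            )
    otsu = otsu_threshold(hist)
    return ThresholdResult(
        threshold=otsu.threshold,
        method="first_minimum",
        candidates=otsu.candidates,
        objective_curve=otsu.objective_curve,
        smoothed_counts=smoothed,
        fallback=True,
    )


def binarize(img: GrayImage, t: ThresholdResult) -> SegmentedImage:
    """Apply h(i,j) = 255 if f(i,j) >= T else 0 (particle class)."""
    labels = np.where(img.pixels >= t.threshold, BACKGROUND, FOREGROUND)
    return SegmentedImage(
        labels=labels.astype(np.uint8),
        threshold_used=t,
        pixel_size_nm=img.pixel_size_nm,
    )


def overlay(img: GrayImage, seg: SegmentedImage) -> np.ndarray:
    """RGB rendering: grayscale background, pure red (255,0,0) particles."""
    if seg.shape != img.shape:
        raise ValidationError(
            f"segmentation shape {seg.shape} does not match image {img.shape}"
        )
    rgb = np.repeat(img.pixels[:, :, np.newaxis], 3, axis=2)
    fg = seg.foreground_mask
    rgb[fg] = (255, 0, 0)
    return rgb
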