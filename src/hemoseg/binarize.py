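"""Whole-cell binarization: Sobel edges + first-valley intensity threshold.

The intensity histogram of a smear is bimodal — a dark cell mode and a
bright background mode.  Cell edges found on the gradient image are first
painted dark onto the intensity image so that touching cells stay connected
through their shared boundary, then the valley between the two histogram
modes thresholds the image and interior holes are filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morph import ConstantImageError, fill_holes, otsu_threshold

__all__ = [
    "NoValleyError",
    "BinarizationResult",
    "first_valley_threshold",
    "binarize_cells",
]

#: moving-average window (bins) applied to the histogram before valley search
VALLEY_SMOOTHING_BINS = 5


class NoValleyError(ValueError):
    """Histogram has fewer than two modes; consider the Otsu fallback."""


@dataclass(frozen=True)
class BinarizationResult:
    gradient: np.ndarray  # Sobel magnitude of the intensity plane
    edge_mask: np.ndarray  # thresholded gradient
    cell_mask: np.ndarray  # final hole-free binary cell map
    valley_threshold: float


def _plateau_extrema(h: np.ndarray) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Plateau-aware local maxima and minima of a 1-D sequence.

    Returns (maxima, minima) as lists of (start, end) index ranges; sequence
    ends count as open boundaries (a run touching the boundary is an
    extremum only relative to its single interior neighbour).
    """
    n = len(h)
    runs: list[tuple[int, int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        runs.append((i, j, h[i]))
        i = j + 1
    maxima, minima = [], []
    for k, (a, b, v) in enumerate(runs):
        left = runs[k - 1][2] if k > 0 else None
        right = runs[k + 1][2] if k + 1 < len(runs) else None
        if (left is None or left < v) and (right is None or right < v):
            maxima.append((a, b))
        if (left is None or left > v) and (right is None or right > v):
            minima.append((a, b))
    return maxima, minima


def first_valley_threshold(hist: np.ndarray, smoothing: int = VALLEY_SMOOTHING_BINS) -> int:
    """Bin index of the valley between the first two modes of a histogram.

    The 256-bin histogram is smoothed with a moving average, the first two
    local maxima (scanning upward from bin 0) are located, and the lowest
    bin between them is returned; a plateau minimum resolves to its midpoint.

    Raises
    ------
    NoValleyError
        If the smoothed histogram is unimodal.
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.ndim != 1 or h.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        h = np.convolve(h, kernel, mode="same")
    maxima, _ = _plateau_extrema(h)
    # ignore empty leading/trailing plateaus at zero height
    maxima = [(a, b) for a, b in maxima if h[a] > 0]
    if len(maxima) < 2:
        raise NoValleyError("histogram is unimodal: no valley between modes")
    m1_end = maxima[0][1]
    m2_start = maxima[1][0]
    if m2_start - m1_end < 2:
        raise NoValleyError("modes are adjacent: no valley between them")
    seg = h[m1_end + 1 : m2_start]
    lo = seg.min()
    idx = np.flatnonzero(seg == lo) + m1_end + 1
    # plateau minimum -> midpoint bin
    return int((idx[0] + idx[-1]) // 2)


def binarize_cells(
    intensity: np.ndarray,
    gradient: np.ndarray,
    threshold_fallback: str | None = None,
    smoothing: int = VALLEY_SMOOTHING_BINS,
) -> BinarizationResult:
    """Binary cell mask from an 8-bit intensity plane and its gradient.

    Edges (gradient above its Otsu threshold) are forced to intensity 0 so
    that the subsequent below-valley threshold captures cell boundaries along
    with cell bodies; interior holes (pale RBC centres) are then filled.

    Parameters
    ----------
    threshold_fallback : {None, "otsu"}
        With ``"otsu"``, a unimodal histogram falls back to Otsu's threshold
        on the edge-modified intensity image instead of raising.
    """
    inten = np.asarray(intensity, dtype=np.float64)
    grad = np.asarray(gradient, dtype=np.float64)
    if inten.shape != grad.shape:
        raise ValueError("intensity and gradient shapes differ")
    grad8 = np.round(np.clip(grad / max(grad.max(), 1e-12) * 255.0, 0, 255)).astype(np.uint8)
    try:
        edge_mask = grad > otsu_threshold(grad8) / 255.0 * grad.max()
    except ConstantImageError:
        edge_mask = np.zeros(grad.shape, dtype=bool)
    modified = inten.copy()
    modified[edge_mask] = 0.0
    mod8 = np.round(np.clip(modified, 0, 255)).astype(np.uint8)
    hist = np.bincount(mod8.ravel(), minlength=256)
    try:
        t = first_valley_threshold(hist, smoothing=smoothing)
    except NoValleyError:
        if threshold_fallback != "otsu":
            raise
        try:
            t = otsu_threshold(mod8)
        except ConstantImageError:
            # featureless image: nothing to segment
            empty = np.zeros(inten.shape, dtype=bool)
            return BinarizationResult(grad, edge_mask, empty, float("nan"))
    cell_mask = fill_holes(mod8 < t)
    return BinarizationResult(grad, edge_mask, cell_mask, float(t))
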