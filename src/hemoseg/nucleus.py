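"""Leukocyte nucleus extraction via saturation/intensity enhancement.

On a stained smear the WBC nucleus is strongly saturated and dark, so the
ratio image S/I is bright exactly on nuclei and near zero on the pale
background, RBCs and cytoplasm.  Otsu thresholding of the ratio then yields
a nucleus map; small high-saturation specks (platelets, which stain the same
purple) are dropped by an area threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morph import ConstantImageError, label_components, otsu_threshold

__all__ = ["HSIPlanes", "NucleusResult", "rgb_to_hsi", "enhance_nucleus", "segment_nucleus"]

#: division guard added to the intensity channel (one 8-bit quantum)
EPSILON_I = 1.0 / 255.0

#: default minimum nucleus area in px^2; separates WBC nuclei from platelets
DEFAULT_MIN_NUCLEUS_AREA = 200.0


@dataclass(frozen=True)
class HSIPlanes:
    """Hue (degrees, [0, 360)), saturation and intensity (both [0, 1])."""

    H: np.ndarray
    S: np.ndarray
    I: np.ndarray


@dataclass(frozen=True)
class NucleusResult:
    enhanced: np.ndarray  # S/I ratio rescaled to [0, 255]
    raw_mask: np.ndarray  # thresholded, before platelet removal
    nucleus_mask: np.ndarray  # after area filtering
    removed_components: int


def rgb_to_hsi(img: np.ndarray) -> HSIPlanes:
    """Classical HSI decomposition: I = mean(R,G,B), S = 1 - min/mean.

    Achromatic pixels (R = G = B) get S = 0; black pixels get S = I = 0.
    The hue plane is computed for completeness but unused downstream.
    """
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {a.shape}")
    rgb = a.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mean = rgb.mean(axis=2)
    mn = rgb.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mean > 0, 1.0 - mn / np.where(mean > 0, mean, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.degrees(np.arccos(np.clip(num / np.where(den > 0, den, 1.0), -1, 1)))
    h = np.where(b <= g, theta, 360.0 - theta)
    h = np.where(den > 0, h, 0.0)
    return HSIPlanes(H=h, S=s, I=mean)


def enhance_nucleus(planes: HSIPlanes) -> np.ndarray:
    """Ratio image S/(I + eps), linearly rescaled to [0, 255].

    High where saturation is high and intensity low — i.e. on stained
    nuclei.  A constant ratio image rescales to all zeros.
    """
    s, i = np.asarray(planes.S, dtype=np.float64), np.asarray(planes.I, dtype=np.float64)
    if s.shape != i.shape:
        raise ValueError("S and I planes differ in shape")
    ratio = s / (i + EPSILON_I)
    lo, hi = ratio.min(), ratio.max()
    if hi == lo:
        return np.zeros_like(ratio)
    return (ratio - lo) / (hi - lo) * 255.0


def segment_nucleus(
    img: np.ndarray,
    min_nucleus_area: float = DEFAULT_MIN_NUCLEUS_AREA,
) -> NucleusResult:
    """Segment WBC nuclei from an RGB smear image.

    The enhanced ratio image is Otsu-thresholded; connected components
    smaller than ``min_nucleus_area`` px^2 (platelets and specks) are then
    removed.  A featureless image yields an empty mask with a warning rather
    than an error.
    """
    planes = rgb_to_hsi(img)
    enhanced = enhance_nucleus(planes)
    try:
        t = otsu_threshold(np.round(enhanced).astype(np.uint8))
    except ConstantImageError:
        warnings.warn("enhanced image is constant; returning empty nucleus mask")
        empty = np.zeros(enhanced.shape, dtype=bool)
        return NucleusResult(enhanced, empty, empty, 0)
    raw_mask = enhanced > t
    labels, n = label_components(raw_mask, connectivity=8)
    if n == 0:
        return NucleusResult(enhanced, raw_mask, raw_mask.copy(), 0)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_nucleus_area) + 1
    nucleus_mask = np.isin(labels, keep) & raw_mask
    return NucleusResult(enhanced, raw_mask, nucleus_mask, int(n - keep.size))
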