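"""Foreground/background marker construction for the second watershed.

The binary cell mask is turned into an (inverted) distance topography; its
regional maxima seed one marker per cell, pseudo-markers created by cell
overlap are pruned with the 2*d_max distance rule, WBC nucleus components
are superimposed as protected markers, and a first watershed on the inverted
topography contributes its ridge lines as the background marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morph import (
    euclidean_distance_transform,
    label_components,
    regional_maxima,
    watershed,
)

__all__ = [
    "DistanceTopography",
    "MarkerSet",
    "MarkerImage",
    "distance_topography",
    "extract_foreground_markers",
    "remove_pseudomarkers",
    "background_markers",
]

DEFAULT_GAUSSIAN_SIGMA = 1.5
#: minimum marker-plateau area; the exact EDT of a circular cell peaks in a
#: 1-px maximum, so anything above 1 deletes genuine seeds
DEFAULT_MIN_MARKER_AREA = 1.0
#: pseudo-marker pruning distance as a fraction of d_max (the largest cell
#: radius); must stay below twice the smallest/largest radius ratio
#: (~0.9 for normal blood) or touching neighbours get pruned
DEFAULT_PSEUDO_MARKER_MULTIPLIER = 0.7
#: minimum distance peak (px) for a candidate seed: sub-cellular maxima
#: (platelets fused onto a cell's mask component) are not cell seeds;
#: 8 px = a 2 um radius at the default 4 px/um rendering scale
DEFAULT_MIN_MARKER_DISTANCE = 8.0


@dataclass(frozen=True)
class DistanceTopography:
    """Distance topography of the denoised cell mask.

    ``d`` is the exact Euclidean distance map; ``grey`` is its integer
    grey-level quantization (a distance *image*), and ``i_dist = 255 - grey``
    (clipped at 0) is the inverted flooding surface of the first watershed:
    cell centres are deep valleys, background is a plateau at 255.
    """

    d: np.ndarray
    grey: np.ndarray
    i_dist: np.ndarray
    smoothed_mask: np.ndarray


@dataclass
class MarkerSet:
    """One candidate seed per cell.

    ``labels`` carries the marker components (1..n); ``points``, ``peaks``
    and ``protected`` are per-marker parallel lists.  ``T`` is the
    pseudo-marker pruning distance, a multiple of the largest cell radius
    ``d_max`` estimated from the distance map.
    """

    labels: np.ndarray
    points: list[tuple[int, int]]
    peaks: list[float]
    protected: list[bool]
    d_max: float
    multiplier: float = DEFAULT_PSEUDO_MARKER_MULTIPLIER

    @property
    def T(self) -> float:
        return self.multiplier * self.d_max

    @property
    def component_mask(self) -> np.ndarray:
        return self.labels > 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MarkerImage:
    """Composite marker map: foreground seed labels 1..n, ridge lines as the
    reserved background label n+1."""

    foreground: np.ndarray
    background: np.ndarray
    composite: np.ndarray
    background_label: int


def distance_topography(cell_mask: np.ndarray, sigma: float = DEFAULT_GAUSSIAN_SIGMA) -> DistanceTopography:
    """Distance map of the Gaussian-denoised cell mask and its inversion.

    The mask is smoothed as a float image and re-thresholded at 0.5 before
    the exact EDT, which removes mask burrs that would spawn spurious
    distance maxima.
    """
    m = np.asarray(cell_mask, dtype=bool)
    if not m.any():
        raise ValueError("cell mask is empty: no distance topography")
    if sigma > 0:
        sm = ndimage.gaussian_filter(m.astype(np.float64), sigma=sigma) > 0.5
    else:
        sm = m.copy()
    if not sm.any():  # smoothing erased everything (specks only)
        raise ValueError("cell mask vanished after denoising")
    d = euclidean_distance_transform(sm)
    grey = np.round(d)
    i_dist = np.clip(255.0 - grey, 0.0, None)
    return DistanceTopography(d=d, grey=grey, i_dist=i_dist, smoothed_mask=sm)


def _representative_point(component: np.ndarray) -> tuple[int, int]:
    """Centroid rounded to the nearest pixel inside the component."""
    ys, xs = np.nonzero(component)
    cy, cx = ys.mean(), xs.mean()
    k = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
    return int(ys[k]), int(xs[k])


def extract_foreground_markers(
    dist: DistanceTopography,
    nucleus_mask: np.ndarray | None = None,
    min_marker_area: float = DEFAULT_MIN_MARKER_AREA,
    multiplier: float = DEFAULT_PSEUDO_MARKER_MULTIPLIER,
    min_marker_distance: float = DEFAULT_MIN_MARKER_DISTANCE,
) -> MarkerSet:
    """Candidate cell seeds from the distance-map regional maxima.

    Regional maxima of the EDT (the residue set of ultimate erosion) with
    area >= ``min_marker_area`` become candidate markers; WBC nucleus
    components are superimposed as protected markers that pseudo-marker
    pruning may never delete.  A candidate belonging to the same cell as a
    nucleus — its peak's inscribed disc B(p, d(p)) reaches the nucleus — is
    absorbed into that protected marker instead of double-seeding the WBC.
    """
    # exact distances for peak detection: grey quantization can fuse the
    # peaks of overlapping cells into one plateau across the saddle
    d = dist.d
    rmax = regional_maxima(d) & (d > 0)
    cand_labels, n_cand = label_components(rmax, connectivity=8)
    nuc = (
        np.zeros(d.shape, dtype=bool)
        if nucleus_mask is None
        else np.asarray(nucleus_mask, dtype=bool)
    )
    if nuc.any() and not nuc.all():
        dist_to_nuc = euclidean_distance_transform(~nuc)
    else:
        dist_to_nuc = None
    labels = np.zeros(d.shape, dtype=np.int64)
    points: list[tuple[int, int]] = []
    peaks: list[float] = []
    protected: list[bool] = []
    next_label = 1
    # protected WBC markers first
    nuc_labels, n_nuc = label_components(nuc, connectivity=8)
    for k in range(1, n_nuc + 1):
        comp = nuc_labels == k
        labels[comp] = next_label
        points.append(_representative_point(comp))
        peaks.append(float(d[comp].max()) if d[comp].size else 0.0)
        protected.append(True)
        next_label += 1
    for k in range(1, n_cand + 1):
        comp = cand_labels == k
        if comp.sum() < min_marker_area:
            continue
        if d[comp].max() < min_marker_distance:
            continue  # sub-cellular bump (e.g. an attached platelet)
        if (comp & nuc).any():  # already represented by a protected marker
            continue
        if dist_to_nuc is not None:
            ys, xs = np.nonzero(comp)
            peak_i = int(np.argmax(d[ys, xs]))
            py, px = ys[peak_i], xs[peak_i]
            if dist_to_nuc[py, px] <= d[py, px]:
                continue  # same cell as a nucleus: absorbed
        labels[comp] = next_label
        points.append(_representative_point(comp))
        peaks.append(float(d[comp].max()))
        protected.append(False)
        next_label += 1
    return MarkerSet(
        labels=labels,
        points=points,
        peaks=peaks,
        protected=protected,
        d_max=float(d.max()),
        multiplier=multiplier,
    )


def remove_pseudomarkers(markers: MarkerSet) -> MarkerSet:
    """Prune overlap-induced duplicate seeds by the T = multiplier * d_max rule.

    Non-protected markers are visited strongest-first (descending distance
    peak); a marker is dropped when a surviving non-protected marker already
    sits closer than T.  Protected (nucleus) markers are never dropped and
    never suppress others; surviving non-protected markers end up pairwise
    >= T apart.
    """
    order = sorted(
        (i for i in range(len(markers)) if not markers.protected[i]),
        key=lambda i: -markers.peaks[i],
    )
    kept: list[int] = []
    removed: set[int] = set()
    for i in order:
        yi, xi = markers.points[i]
        ok = True
        for j in kept:
            yj, xj = markers.points[j]
            if np.hypot(yi - yj, xi - xj) < markers.T:
                ok = False
                break
        if ok:
            kept.append(i)
        else:
            removed.add(i)
    if not removed:
        return markers
    keep_idx = [i for i in range(len(markers)) if i not in removed]
    labels = np.zeros_like(markers.labels)
    for new, old in enumerate(keep_idx, start=1):
        labels[markers.labels == old + 1] = new
    return MarkerSet(
        labels=labels,
        points=[markers.points[i] for i in keep_idx],
        peaks=[markers.peaks[i] for i in keep_idx],
        protected=[markers.protected[i] for i in keep_idx],
        d_max=markers.d_max,
        multiplier=markers.multiplier,
    )


def background_markers(
    i_dist: np.ndarray, fg: MarkerSet, cell_mask: np.ndarray | None = None
) -> MarkerImage:
    """Ridge lines of the first watershed on the inverted distance map.

    Flooding ``i_dist`` from the foreground seeds partitions the image into
    one region per cell; the watershed lines run through the background
    between cells and become the background marker.  When ``cell_mask`` is
    given, ridge pixels falling inside cells (the lines crossing the necks
    of adherent clusters) are dropped — the background marker marks
    background; necks are split by the competing cell seeds instead.  The
    composite map holds the foreground seed components plus the ridge as a
    reserved extra label.
    """
    if len(fg) == 0:
        raise ValueError("no foreground markers")
    _, ridge = watershed(np.asarray(i_dist, dtype=np.float64), fg.labels)
    # the frame border belongs to the background marker too: a lone cell
    # produces no ridge at all, and border pixels are background anyway
    border = np.zeros_like(ridge)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    ridge = ridge | border
    if cell_mask is not None:
        ridge = ridge & ~np.asarray(cell_mask, dtype=bool)
    ridge = ridge & ~(fg.labels > 0)
    bg_label = len(fg) + 1
    composite = fg.labels.copy()
    composite[ridge] = bg_label
    return MarkerImage(
        foreground=fg.labels,
        background=ridge,
        composite=composite,
        background_label=bg_label,
    )
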