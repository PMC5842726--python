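"""Gradient-surface reconstruction and the final marker-controlled watershed.

The Sobel gradient of the intensity plane is a topography whose catchment
basins are cell interiors and background patches.  Shallow noise basins are
filled with the H-minima transform (basin depth threshold t_i, default 3
grey levels), the remaining minima are pinned to the composite marker map,
and the watershed of the reconstructed surface traces one closed contour
per cell along the gradient crest lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .markers import MarkerImage
from .morph import compact_labels, h_minima, impose_minima, watershed

__all__ = [
    "SegmentationResult",
    "basin_depth",
    "modify_gradient",
    "segment_cells",
    "moore_contour",
    "DEFAULT_T_I",
]

#: default basin-depth threshold (grey levels); the useful range is 2-4
DEFAULT_T_I = 3.0
T_I_RANGE = (2.0, 4.0)

_MOORE_CW = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class SegmentationResult:
    labels: np.ndarray  # 0 = background/ridge, 1..n = cells
    contours: dict[int, list[tuple[int, int]]]
    modified_gradient: np.ndarray
    t_i: float

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


def basin_depth(img: np.ndarray, basin_component: np.ndarray) -> float:
    """Depth of a regional-minimum plateau: min over its outer 8-boundary
    minus the plateau value.

    Raises
    ------
    ValueError
        If the component is not a regional-minimum plateau of ``img``.
    """
    a = np.asarray(img, dtype=np.float64)
    comp = np.asarray(basin_component, dtype=bool)
    if comp.shape != a.shape or not comp.any():
        raise ValueError("invalid basin component")
    inside = a[comp]
    v = inside.min()
    if inside.max() != v:
        raise ValueError("component is not a plateau")
    H, W = a.shape
    ys, xs = np.nonzero(comp)
    boundary_vals: list[float] = []
    for y, x in zip(ys.tolist(), xs.tolist()):
        for dy, dx in _MOORE_CW:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and not comp[ny, nx]:
                boundary_vals.append(a[ny, nx])
    if not boundary_vals:
        return 0.0  # plateau fills the whole frame
    if min(boundary_vals) <= v:
        raise ValueError("component is not a regional minimum")
    return float(min(boundary_vals) - v)


def modify_gradient(grad: np.ndarray, markers: MarkerImage, t_i: float = DEFAULT_T_I) -> np.ndarray:
    """Reconstructed gradient surface with minima only at the markers.

    H-minima first removes basins shallower than ``t_i``, then minima
    imposition pins the surviving minima to the foreground-seed and
    background-ridge components.  Values of ``t_i`` outside the usual 2-4
    range are accepted with a warning.
    """
    if t_i <= 0:
        raise ValueError("t_i must be positive")
    if not (T_I_RANGE[0] <= t_i <= T_I_RANGE[1]):
        warnings.warn(f"t_i={t_i} outside the usual range {T_I_RANGE}")
    marker_mask = (markers.foreground > 0) | markers.background
    if not marker_mask.any():
        raise ValueError("marker image is empty")
    return impose_minima(h_minima(np.asarray(grad, dtype=np.float64), t_i), marker_mask)


def moore_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed outer boundary of a connected region by clockwise
    Moore-neighbour tracing (Jacob's stopping criterion)."""
    m = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        return []
    if ys.size == 1:
        return [(int(ys[0]), int(xs[0]))]
    # start at the topmost-leftmost pixel; entered "from the left"
    order = np.lexsort((xs, ys))
    sy, sx = int(ys[order[0]]), int(xs[order[0]])
    H, W = m.shape

    def inside(y: int, x: int) -> bool:
        return 0 <= y < H and 0 <= x < W and m[y, x]

    contour: list[tuple[int, int]] = [(sy, sx)]
    # backtrack = the outside pixel we came from (left of start)
    cur = (sy, sx)
    back = (sy, sx - 1)
    start_state = None
    while True:
        # scan the Moore neighbourhood clockwise starting just after `back`
        bidx = _MOORE_CW.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            dy, dx = _MOORE_CW[(bidx + k) % 8]
            cand = (cur[0] + dy, cur[1] + dx)
            if inside(*cand):
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel (cannot happen: size > 1 & connected)
            break
        state = (cur, nxt)
        if start_state is None:
            start_state = state
        elif state == start_state:
            break
        cur = nxt
        if contour[-1] != cur:
            contour.append(cur)
        if len(contour) > 4 * (H * W):
            raise RuntimeError("contour tracing failed to terminate")
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return contour


def segment_cells(
    grad_mark: np.ndarray, markers: MarkerImage, t_i: float = DEFAULT_T_I
) -> SegmentationResult:
    """Final watershed of the reconstructed gradient surface.

    Regions flooded from the background (ridge) marker become label 0; the
    remaining cell labels are compacted to 1..n and each cell's outer
    boundary is traced as a closed pixel chain.
    """
    labels, ridge = watershed(np.asarray(grad_mark, dtype=np.float64), markers.composite)
    labels = labels.copy()
    labels[labels == markers.background_label] = 0
    labels[ridge] = 0
    labels = compact_labels(labels)
    contours = {
        int(k): moore_contour(labels == k) for k in np.unique(labels) if k > 0
    }
    return SegmentationResult(
        labels=labels,
        contours=contours,
        modified_gradient=np.asarray(grad_mark, dtype=np.float64),
        t_i=t_i,
    )
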