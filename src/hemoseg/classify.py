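"""WBC/RBC classification of segmented cells by nucleus containment.

Leukocytes are nucleated and erythrocytes are not, so a segmented cell is a
WBC exactly when it overlaps the nucleus mask.  A nucleus split across two
cell labels credits only the label with the larger overlap, so one nucleus
can never produce two WBCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .morph import label_components
from .segment import SegmentationResult, moore_contour

__all__ = ["CellRecord", "classify_cells", "records_to_frame"]

WBC = "WBC"
RBC = "RBC"


@dataclass(frozen=True)
class CellRecord:
    label: int
    cell_class: str  # "WBC" or "RBC"
    area: float  # px^2
    centroid: tuple[float, float]  # (row, col)
    nucleus_overlap: float  # px^2 credited to this cell
    contour: list[tuple[int, int]]


def classify_cells(
    labels: np.ndarray,
    nucleus_mask: np.ndarray,
    min_overlap: float = 1.0,
    contours: dict[int, list[tuple[int, int]]] | None = None,
) -> list[CellRecord]:
    """One record per positive label; class WBC iff the credited nucleus
    overlap reaches ``min_overlap`` px^2 (default: any containment)."""
    lab = np.asarray(labels)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if lab.shape != nuc.shape:
        raise ValueError("label map and nucleus mask shapes differ")
    ids = [int(k) for k in np.unique(lab) if k > 0]
    if not ids:
        return []
    # credit each nucleus component to the single cell with the largest overlap
    credited = {k: 0.0 for k in ids}
    nuc_labels, n_nuc = label_components(nuc, connectivity=8)
    for k in range(1, n_nuc + 1):
        comp = nuc_labels == k
        over = lab[comp]
        over = over[over > 0]
        if over.size == 0:
            continue
        counts = np.bincount(over)
        winner = int(np.argmax(counts))
        credited[winner] += float(counts[winner])
    records = []
    for k in ids:
        region = lab == k
        area = float(region.sum())
        cy, cx = ndimage.center_of_mass(region)
        overlap = credited[k]
        contour = (
            contours.get(k) if contours is not None else moore_contour(region)
        ) or []
        records.append(
            CellRecord(
                label=k,
                cell_class=WBC if overlap >= min_overlap else RBC,
                area=area,
                centroid=(float(cy), float(cx)),
                nucleus_overlap=overlap,
                contour=contour,
            )
        )
    return records


def classify_segmentation(
    seg: SegmentationResult, nucleus_mask: np.ndarray, min_overlap: float = 1.0
) -> list[CellRecord]:
    """Convenience wrapper reusing the contours already traced."""
    return classify_cells(seg.labels, nucleus_mask, min_overlap, contours=seg.contours)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Per-cell table: label, class, area, centroid, nucleus overlap."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "cell_class": [r.cell_class for r in records],
            "area": [r.area for r in records],
            "centroid_row": [r.centroid[0] for r in records],
            "centroid_col": [r.centroid[1] for r in records],
            "nucleus_overlap": [r.nucleus_overlap for r in records],
        }
    )
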