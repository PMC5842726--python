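"""Image and table I/O: 8-bit RGB in; label TIFF, overlay PNG and CSV out."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .classify import CellRecord, records_to_frame

__all__ = [
    "read_rgb",
    "write_label_tiff",
    "read_label_tiff",
    "write_mask_png",
    "write_overlay_png",
    "write_records_csv",
]

RED = (255, 0, 0)
BLUE = (0, 0, 255)


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG); alpha is dropped, greyscale
    is replicated to three channels."""
    a = iio.imread(path)
    if a.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got {a.dtype}")
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError(f"{path}: not an RGB image (shape {a.shape})")
    return np.ascontiguousarray(a[..., :3])


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values do not fit uint16")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def write_mask_png(path: str | Path, mask_or_map: np.ndarray) -> None:
    a = np.asarray(mask_or_map)
    if a.dtype == bool:
        a = a.astype(np.uint8) * 255
    else:
        a = np.clip(np.round(a), 0, 255).astype(np.uint8)
    iio.imwrite(str(path), a)


def write_overlay_png(
    path: str | Path,
    img: np.ndarray,
    records: list[CellRecord],
    nucleus_mask: np.ndarray | None = None,
) -> None:
    """Input image with red cell outlines and blue nucleus outlines."""
    from .segment import moore_contour

    out = np.asarray(img).copy()
    for r in records:
        for y, x in r.contour:
            out[y, x] = RED
    if nucleus_mask is not None and np.asarray(nucleus_mask).any():
        from .morph import label_components

        lab, n = label_components(nucleus_mask, connectivity=8)
        for k in range(1, n + 1):
            for y, x in moore_contour(lab == k):
                out[y, x] = BLUE
    iio.imwrite(str(path), out)


def write_records_csv(path: str | Path, records: list[CellRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)
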