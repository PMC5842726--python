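"""End-to-end orchestration: nucleus -> binarization -> markers -> watershed
-> classification, with one configuration object and per-stage logging.

The pipeline is fully deterministic: no stage consumes randomness, so
repeated runs on the same image and configuration are bit-identical.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .binarize import BinarizationResult, NoValleyError, binarize_cells
from .classify import CellRecord, classify_segmentation
from .markers import (
    DEFAULT_GAUSSIAN_SIGMA,
    DEFAULT_MIN_MARKER_AREA,
    DEFAULT_MIN_MARKER_DISTANCE,
    DEFAULT_PSEUDO_MARKER_MULTIPLIER,
    MarkerImage,
    MarkerSet,
    background_markers,
    distance_topography,
    extract_foreground_markers,
    remove_pseudomarkers,
)
from .morph import sobel_gradient
from .nucleus import DEFAULT_MIN_NUCLEUS_AREA, NucleusResult, rgb_to_hsi, segment_nucleus
from .segment import DEFAULT_T_I, SegmentationResult, modify_gradient, segment_cells

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline"]

logger = logging.getLogger("hemoseg")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a remedy hint."""

    def __init__(self, stage: str, cause: BaseException, hint: str = ""):
        self.stage = stage
        self.hint = hint
        msg = f"stage '{stage}' failed: {cause}"
        if hint:
            msg += f" (hint: {hint})"
        super().__init__(msg)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, defaulting to the published values
    where printed (t_i = 3, pseudo-marker threshold T = 2 * d_max) and to
    package defaults elsewhere."""

    min_nucleus_area: float = DEFAULT_MIN_NUCLEUS_AREA
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA
    t_i: float = DEFAULT_T_I
    pseudo_marker_multiplier: float = DEFAULT_PSEUDO_MARKER_MULTIPLIER
    min_marker_area: float = DEFAULT_MIN_MARKER_AREA
    min_marker_distance: float = DEFAULT_MIN_MARKER_DISTANCE
    #: regional (area) threshold removing platelet-sized components from the
    #: cell mask, px^2; platelets are out of analysis scope
    min_cell_area: float = 150.0
    valley_smoothing: int = 5
    threshold_fallback: str | None = None  # None or "otsu"
    overlap_threshold: float = 0.5
    min_class_overlap: float = 1.0
    seed: int = 0  # used only by the synthetic generator

    def __post_init__(self) -> None:
        if self.t_i <= 0:
            raise ValueError("t_i must be positive")
        if self.pseudo_marker_multiplier <= 0:
            raise ValueError("pseudo_marker_multiplier must be positive")
        if self.min_nucleus_area < 0 or self.min_marker_area < 0:
            raise ValueError("area thresholds must be non-negative")
        if self.threshold_fallback not in (None, "otsu"):
            raise ValueError("threshold_fallback must be None or 'otsu'")


def _empty_result(shape: tuple[int, int], t_i: float) -> SegmentationResult:
    return SegmentationResult(
        labels=np.zeros(shape, dtype=np.int64),
        contours={},
        modified_gradient=np.zeros(shape, dtype=np.float64),
        t_i=t_i,
    )


@dataclass
class PipelineResult:
    segmentation: SegmentationResult
    records: list[CellRecord]
    nucleus: NucleusResult
    binarization: BinarizationResult | None = None
    marker_set: MarkerSet | None = None
    marker_image: MarkerImage | None = None
    gradient: np.ndarray | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        # allows ``seg, records = run_pipeline(...)``
        return iter((self.segmentation, self.records))


def run_pipeline(img: np.ndarray, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Segment and classify every cell of an 8-bit RGB smear image.

    A featureless image (no histogram valley and no nuclei) yields an empty
    result with a warning rather than an error; genuine stage failures raise
    :class:`StageError` naming the stage.
    """
    cfg = cfg or PipelineConfig()
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise StageError("input", ValueError(f"expected HxWx3 RGB, got {a.shape}"))
    shape = a.shape[:2]
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = time.perf_counter() - self.t0
                return False

        return _T()

    with timed("nucleus"):
        try:
            nucleus = segment_nucleus(a, min_nucleus_area=cfg.min_nucleus_area)
        except Exception as e:  # noqa: BLE001
            raise StageError("nucleus", e) from e
    logger.info("nucleus: %d px, %d platelet-sized component(s) removed",
                int(nucleus.nucleus_mask.sum()), nucleus.removed_components)

    with timed("binarization"):
        intensity8 = rgb_to_hsi(a).I * 255.0
        try:
            grad = sobel_gradient(intensity8)
            binz = binarize_cells(
                intensity8,
                grad,
                threshold_fallback=cfg.threshold_fallback,
                smoothing=cfg.valley_smoothing,
            )
        except NoValleyError as e:
            if not nucleus.nucleus_mask.any():
                warnings.warn("featureless image: no histogram valley and no "
                              "nuclei; returning an empty segmentation")
                return PipelineResult(_empty_result(shape, cfg.t_i), [], nucleus,
                                      timings=timings)
            raise StageError("binarization", e,
                             hint="pass threshold_fallback='otsu' "
                                  "(CLI: --threshold-fallback otsu)") from e
        except Exception as e:  # noqa: BLE001
            raise StageError("binarization", e) from e
    logger.info("binarization: %d cell pixels, valley=%s",
                int(binz.cell_mask.sum()), binz.valley_threshold)
    if cfg.min_cell_area > 0 and binz.cell_mask.any():
        # platelet removal: drop platelet-sized mask components
        from .morph import label_components

        comp, n = label_components(binz.cell_mask, connectivity=8)
        areas = np.bincount(comp.ravel(), minlength=n + 1)
        keep = np.flatnonzero(areas >= cfg.min_cell_area)
        keep = keep[keep > 0]
        binz = BinarizationResult(
            binz.gradient,
            binz.edge_mask,
            np.isin(comp, keep),
            binz.valley_threshold,
        )

    if not binz.cell_mask.any():
        warnings.warn("no cell pixels found; returning an empty segmentation")
        return PipelineResult(_empty_result(shape, cfg.t_i), [], nucleus,
                              binarization=binz, gradient=grad, timings=timings)

    with timed("markers"):
        try:
            topo = distance_topography(binz.cell_mask, sigma=cfg.gaussian_sigma)
        except ValueError as e:
            warnings.warn(f"distance topography degenerate ({e}); "
                          "returning an empty segmentation")
            return PipelineResult(_empty_result(shape, cfg.t_i), [], nucleus,
                                  binarization=binz, gradient=grad, timings=timings)
        try:
            ms = extract_foreground_markers(
                topo,
                nucleus.nucleus_mask,
                min_marker_area=cfg.min_marker_area,
                multiplier=cfg.pseudo_marker_multiplier,
                min_marker_distance=cfg.min_marker_distance,
            )
            ms = remove_pseudomarkers(ms)
            if len(ms) == 0:
                warnings.warn("no foreground markers; returning an empty segmentation")
                return PipelineResult(_empty_result(shape, cfg.t_i), [], nucleus,
                                      binarization=binz, marker_set=ms,
                                      gradient=grad, timings=timings)
            mi = background_markers(topo.i_dist, ms, cell_mask=topo.smoothed_mask)
        except Exception as e:  # noqa: BLE001
            raise StageError("markers", e) from e
    logger.info("markers: %d foreground seed(s), T=%.1f", len(ms), ms.T)

    with timed("watershed"):
        try:
            grad_mark = modify_gradient(grad, mi, t_i=cfg.t_i)
            seg = segment_cells(grad_mark, mi, t_i=cfg.t_i)
        except Exception as e:  # noqa: BLE001
            raise StageError("watershed", e) from e
    logger.info("watershed: %d cell(s)", seg.n_cells)

    with timed("classification"):
        try:
            records = classify_segmentation(
                seg, nucleus.nucleus_mask, min_overlap=cfg.min_class_overlap
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("classification", e) from e
    n_wbc = sum(r.cell_class == "WBC" for r in records)
    logger.info("classification: %d WBC, %d RBC", n_wbc, len(records) - n_wbc)

    return PipelineResult(
        segmentation=seg,
        records=records,
        nucleus=nucleus,
        binarization=binz,
        marker_set=ms,
        marker_image=mi,
        gradient=grad,
        timings=timings,
    )
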