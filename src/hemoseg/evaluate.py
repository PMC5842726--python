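"""Instance-matching segmentation metrics: one-to-one, over-segmentation,
under-segmentation and fault rates.

Matching is Hoover-style on the ground-truth x prediction overlap matrix.
With threshold ``thr`` (default 0.5):

* a ground-truth instance is *one-to-one* when exactly one prediction covers
  at least ``thr`` of it and that prediction is in turn majority-covered by
  the instance;
* *over-segmented* when two or more predictions each cover at least
  ``thr/2`` of it;
* *under-segmented* when some prediction covers at least ``thr/2`` of it
  and of at least one other ground-truth instance;
* *fault* (missed) otherwise.

Every ground-truth instance lands in exactly one category, so the four
rates sum to 1 per class.  Split/merge evidence outranks the one-to-one
test (precedence: overseg, underseg, one-to-one, fault): a merged pred that
still majority-covers its larger constituent must not count as a match.  Predictions matched to nothing are reported separately as
``n_spurious`` rather than folded into the fault rate, keeping the
per-ground-truth accounting exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import GroundTruth

__all__ = ["ClassReport", "EvalReport", "match_segments", "mean_matched_jaccard"]

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassReport:
    cell_class: str
    n_gt: int
    n_pred: int
    n_one_to_one: int
    n_overseg: int
    n_underseg: int
    n_fault: int
    n_spurious: int

    def _rate(self, n: int) -> float:
        return n / self.n_gt if self.n_gt else 0.0

    @property
    def one_to_one_rate(self) -> float:
        return self._rate(self.n_one_to_one)

    @property
    def overseg_rate(self) -> float:
        return self._rate(self.n_overseg)

    @property
    def underseg_rate(self) -> float:
        return self._rate(self.n_underseg)

    @property
    def fault_rate(self) -> float:
        return self._rate(self.n_fault)


@dataclass(frozen=True)
class EvalReport:
    per_class: dict[str, ClassReport]
    #: per gt id: category string
    gt_category: dict[int, str]
    #: per gt id: matched pred ids (the covering set used by its category)
    matching: dict[int, list[int]]
    #: one-to-one pairs (gt id, pred id)
    pairs: list[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, r in self.per_class.items():
            rows.append(
                {
                    "cell_class": cls,
                    "n_gt": r.n_gt,
                    "n_pred": r.n_pred,
                    "one_to_one": r.one_to_one_rate,
                    "overseg": r.overseg_rate,
                    "underseg": r.underseg_rate,
                    "fault": r.fault_rate,
                    "spurious_preds": r.n_spurious,
                }
            )
        return pd.DataFrame(rows)


def _overlap_matrix(pred: np.ndarray, gt: np.ndarray, gt_ids, pred_ids):
    """Pixel-overlap counts indexed by (gt id, pred id)."""
    out = {}
    for g in gt_ids:
        region = gt == g
        vals, counts = np.unique(pred[region], return_counts=True)
        for v, c in zip(vals.tolist(), counts.tolist()):
            if v > 0:
                out[(g, v)] = c
    return out


def match_segments(
    pred: np.ndarray,
    gt: GroundTruth | np.ndarray,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    gt_classes: dict[int, str] | None = None,
    pred_classes: dict[int, str] | None = None,
) -> EvalReport:
    """Score a predicted label map against ground truth.

    ``gt`` may be a :class:`~hemoseg.synth.GroundTruth` (platelet instances
    are excluded: the pipeline only segments cells) or a raw label map with
    an optional ``gt_classes`` mapping.  A prediction's class, used only for
    per-class ``n_pred``/spurious accounting, is taken from ``pred_classes``
    when given, else inherited from the ground-truth instance it overlaps
    most.
    """
    p = np.asarray(pred)
    if isinstance(gt, GroundTruth):
        g = gt.instance_labels
        keep = set(gt.cell_ids())
        classes = {i + 1: c for i, c in enumerate(gt.classes) if i + 1 in keep}
        g = np.where(np.isin(g, sorted(keep)), g, 0)
    else:
        g = np.asarray(gt)
        classes = gt_classes or {int(k): "cell" for k in np.unique(g) if k > 0}
    if p.shape != g.shape:
        raise ValueError("pred and gt label maps differ in shape")
    thr = float(overlap_threshold)
    gt_ids = sorted(classes)
    pred_ids = [int(k) for k in np.unique(p) if k > 0]
    ov = _overlap_matrix(p, g, gt_ids, pred_ids)
    gt_area = {k: int((g == k).sum()) for k in gt_ids}
    pred_area = {k: int((p == k).sum()) for k in pred_ids}

    gt_category: dict[int, str] = {}
    matching: dict[int, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    matched_preds: set[int] = set()

    # pass 1: overseg (>= 2 preds each covering >= thr/2 of the gt)
    for gid in gt_ids:
        halves = [
            pid for pid in pred_ids if ov.get((gid, pid), 0) >= 0.5 * thr * gt_area[gid]
        ]
        if len(halves) >= 2:
            gt_category[gid] = "overseg"
            matching[gid] = halves
            matched_preds.update(halves)
    # pass 2: underseg (one pred covering >= thr/2 of >= 2 gts)
    gt_halves_by_pred: dict[int, list[int]] = {}
    for gid in gt_ids:
        for pid in pred_ids:
            if ov.get((gid, pid), 0) >= 0.5 * thr * gt_area[gid]:
                gt_halves_by_pred.setdefault(pid, []).append(gid)
    for pid, gids in gt_halves_by_pred.items():
        if len(gids) >= 2:
            for gid in gids:
                if gid not in gt_category:
                    gt_category[gid] = "underseg"
                    matching[gid] = [pid]
                    matched_preds.add(pid)
    # pass 3: one-to-one (exactly one covering pred, majority-covered by gt)
    for gid in gt_ids:
        if gid in gt_category:
            continue
        covering = [
            pid for pid in pred_ids if ov.get((gid, pid), 0) >= thr * gt_area[gid]
        ]
        if len(covering) == 1:
            pid = covering[0]
            if ov[(gid, pid)] >= 0.5 * pred_area[pid]:
                gt_category[gid] = "one_to_one"
                matching[gid] = [pid]
                pairs.append((gid, pid))
                matched_preds.add(pid)
    # pass 4: fault (missed)
    for gid in gt_ids:
        if gid not in gt_category:
            gt_category[gid] = "fault"
            matching[gid] = []

    # prediction class assignment for per-class spurious accounting
    if pred_classes is None:
        pred_classes = {}
        for pid in pred_ids:
            best, best_ov = None, 0
            for gid in gt_ids:
                o = ov.get((gid, pid), 0)
                if o > best_ov:
                    best, best_ov = gid, o
            pred_classes[pid] = classes[best] if best is not None else "spurious"

    class_names = sorted(set(classes.values()) | {c for c in pred_classes.values() if c != "spurious"})
    per_class = {}
    for cls in class_names:
        cls_gt = [gid for gid in gt_ids if classes[gid] == cls]
        cls_pred = [pid for pid in pred_ids if pred_classes.get(pid) == cls]
        cat = {k: sum(1 for gid in cls_gt if gt_category[gid] == k) for k in ("one_to_one", "overseg", "underseg", "fault")}
        per_class[cls] = ClassReport(
            cell_class=cls,
            n_gt=len(cls_gt),
            n_pred=len(cls_pred),
            n_one_to_one=cat["one_to_one"],
            n_overseg=cat["overseg"],
            n_underseg=cat["underseg"],
            n_fault=cat["fault"],
            n_spurious=sum(1 for pid in cls_pred if pid not in matched_preds),
        )
    return EvalReport(per_class=per_class, gt_category=gt_category, matching=matching, pairs=pairs)


def mean_matched_jaccard(pred: np.ndarray, gt: GroundTruth | np.ndarray, report: EvalReport) -> float:
    """Mean intersection-over-union over the one-to-one matched pairs."""
    p = np.asarray(pred)
    g = gt.instance_labels if isinstance(gt, GroundTruth) else np.asarray(gt)
    if not report.pairs:
        return float("nan")
    vals = []
    for gid, pid in report.pairs:
        a = g == gid
        b = p == pid
        vals.append((a & b).sum() / (a | b).sum())
    return float(np.mean(vals))
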