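"""CLEAR-MOT evaluation of tracker output against ground truth.

Per frame, predicted boxes are matched one-to-one to ground-truth boxes by
intersection-over-union (IoU).  Correspondences from the previous frame are
kept first whenever they are still above the matching threshold (the
continuity rule); the remaining boxes are then assigned optimally, maximising
the number of above-threshold matches and, among those, the total IoU.
Unmatched ground-truth boxes are misses (FN), unmatched predictions are false
positives (FP), and a ground-truth track whose matched prediction ID differs
from its last matched ID incurs an identity switch (IDSW).  Summary metrics:

    MOTA = 1 - (FN + FP + IDSW) / GT          (GT = ground-truth records)
    MOTP = mean IoU over all matches          (higher is better)

A centre-distance MOTP variant (mean pixel distance of matched centres) is
reported alongside.  Ground-truth records with confidence flag 0 are excluded
from evaluation; prediction confidences are ignored (no score thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import dist
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DomainError, UndefinedStatisticError
from .mot_io import BoxRecord, SequenceAnnotations

__all__ = ["FrameMatching", "MetricsReport", "iou", "match_frame", "evaluate"]

_BIG_M = 1e9  # cost for below-threshold pairs: never preferred over leaving unmatched


def iou(a: BoxRecord, b: BoxRecord) -> float:
    """Intersection-over-union of two axis-aligned boxes, in [0, 1]."""
    ix = max(0.0, min(a.left + a.width, b.left + b.width) - max(a.left, b.left))
    iy = max(0.0, min(a.top + a.height, b.top + b.height) - max(a.top, b.top))
    inter = ix * iy
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


@dataclass
class FrameMatching:
    """Outcome of matching one frame."""

    frame: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)  # (gt_id, pred_id, iou)
    false_positives: list[int] = field(default_factory=list)
    misses: list[int] = field(default_factory=list)
    id_switches: int = 0


@dataclass(frozen=True)
class MetricsReport:
    mota: float
    motp: float
    fp: int
    fn: int
    idsw: int
    gt: int
    n_matches: int
    motp_distance: float

    def as_dict(self) -> dict:
        return {
            "MOTA": self.mota,
            "MOTP": self.motp,
            "FP": self.fp,
            "FN": self.fn,
            "IDSW": self.idsw,
            "GT": self.gt,
            "matches": self.n_matches,
            "MOTP_distance_px": self.motp_distance,
        }


def match_frame(
    gt_boxes: Sequence[BoxRecord],
    pred_boxes: Sequence[BoxRecord],
    prev_correspondence: Mapping[int, int] | None = None,
    threshold: float = 0.5,
) -> FrameMatching:
    """Match one frame's predictions to its ground truth.

    Existing (gt_id -> pred_id) correspondences are kept when both boxes are
    present and still overlap at or above ``threshold``; the remaining boxes
    get a fresh optimal assignment.  On small inputs the result equals
    brute-force enumeration over all one-to-one assignments.
    """
    if not (0 < threshold <= 1):
        raise DomainError("threshold must lie in (0, 1]")
    prev = dict(prev_correspondence or {})
    frame = gt_boxes[0].frame if gt_boxes else (pred_boxes[0].frame if pred_boxes else 0)
    result = FrameMatching(frame=frame)

    gt_by_id = {r.track_id: r for r in gt_boxes}
    pred_by_id = {r.track_id: r for r in pred_boxes}
    if len(gt_by_id) != len(gt_boxes) or len(pred_by_id) != len(pred_boxes):
        raise DomainError("duplicate track ids within one frame")

    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    # continuity rule: persist still-valid correspondences before fresh assignment
    for gid, pid in prev.items():
        if gid in gt_by_id and pid in pred_by_id:
            ov = iou(gt_by_id[gid], pred_by_id[pid])
            if ov >= threshold:
                result.matches.append((gid, pid, ov))
                matched_gt.add(gid)
                matched_pred.add(pid)

    free_gt = [g for g in gt_by_id if g not in matched_gt]
    free_pred = [p for p in pred_by_id if p not in matched_pred]
    if free_gt and free_pred:
        cost = np.full((len(free_gt), len(free_pred)), _BIG_M)
        ov_mat = np.zeros_like(cost)
        for i, gid in enumerate(free_gt):
            for j, pid in enumerate(free_pred):
                ov = iou(gt_by_id[gid], pred_by_id[pid])
                ov_mat[i, j] = ov
                if ov >= threshold:
                    cost[i, j] = 1.0 - ov
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < _BIG_M:
                result.matches.append((free_gt[i], free_pred[j], float(ov_mat[i, j])))
                matched_gt.add(free_gt[i])
                matched_pred.add(free_pred[j])

    result.matches.sort()
    result.misses = sorted(g for g in gt_by_id if g not in matched_gt)
    result.false_positives = sorted(p for p in pred_by_id if p not in matched_pred)
    return result


def evaluate(
    gt: SequenceAnnotations,
    pred: SequenceAnnotations,
    threshold: float = 0.5,
) -> MetricsReport:
    """CLEAR-MOT metrics of a predicted track set against ground truth.

    Ground-truth records with confidence flag 0 are excluded.  The
    correspondence memory spans gaps: a ground-truth track re-matched after
    frames of absence is compared against its last matched prediction ID for
    identity-switch counting.
    """
    gt_records = [r for r in gt if r.confidence != 0]
    if not gt_records:
        raise UndefinedStatisticError("empty ground truth: MOTA is undefined")
    pred_records = list(pred)

    gt_frames: dict[int, list[BoxRecord]] = {}
    for r in gt_records:
        gt_frames.setdefault(r.frame, []).append(r)
    pred_frames: dict[int, list[BoxRecord]] = {}
    for r in pred_records:
        pred_frames.setdefault(r.frame, []).append(r)

    corr: dict[int, int] = {}       # active correspondences (continuity rule)
    last_match: dict[int, int] = {}  # last matched pred id per gt track (IDSW)
    fp = fn = idsw = 0
    overlaps: list[float] = []
    distances: list[float] = []

    for frame in sorted(set(gt_frames) | set(pred_frames)):
        g = gt_frames.get(frame, [])
        p = pred_frames.get(frame, [])
        fm = match_frame(g, p, corr, threshold)
        g_by_id = {r.track_id: r for r in g}
        p_by_id = {r.track_id: r for r in p}
        new_corr: dict[int, int] = {}
        for gid, pid, ov in fm.matches:
            if gid in last_match and last_match[gid] != pid:
                idsw += 1
                fm.id_switches += 1
            last_match[gid] = pid
            new_corr[gid] = pid
            overlaps.append(ov)
            distances.append(dist(g_by_id[gid].center, p_by_id[pid].center))
        fn += len(fm.misses)
        fp += len(fm.false_positives)
        corr = new_corr

    n_gt = len(gt_records)
    n_matches = len(overlaps)
    mota = 1.0 - (fn + fp + idsw) / n_gt
    motp = float(np.mean(overlaps)) if overlaps else float("nan")
    motp_d = float(np.mean(distances)) if distances else float("nan")
    return MetricsReport(
        mota=mota, motp=motp, fp=fp, fn=fn, idsw=idsw,
        gt=n_gt, n_matches=n_matches, motp_distance=motp_d,
    )
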