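"""Automated quality control for ground-truth trajectory annotations.

Mirrors the two levels of human review used when the dataset was marked: a
coarse sequence-level summary (frame/track/record counts) and a fine
frame-level pass that localises suspicious segments for remarking.  Issues are
data, not exceptions: ``error`` severity marks violated structural invariants
(duplicate (frame, id) pairs, non-positive boxes, a ground-truth confidence
flag outside {0, 1}), while ``warning`` marks suspicious-but-legal patterns
(track gaps — outdoor ants legitimately leave the scene; out-of-frame box
centres; single-frame jumps larger than a body-length threshold).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .mot_io import GROUND_TRUTH, SequenceAnnotations, SequenceMeta

__all__ = [
    "QCIssue",
    "SequenceSummary",
    "check_sequence",
    "summarize",
    "manifest_totals",
    "segment_report",
    "TELEPORT_BODY_LENGTHS",
]

Severity = Literal["error", "warning"]
IssueKind = Literal[
    "duplicate_pair",
    "nonpositive_box",
    "out_of_frame",
    "id_gap",
    "teleport",
    "bad_confidence",
]

#: default single-frame displacement threshold, in body lengths per frame
TELEPORT_BODY_LENGTHS = 5.0


@dataclass(frozen=True)
class QCIssue:
    severity: Severity
    kind: IssueKind
    frame: int
    track_id: int
    detail: str


@dataclass(frozen=True)
class SequenceSummary:
    n_frames_annotated: int
    n_tracks: int
    n_records: int
    records_per_frame: dict[int, int]


def check_sequence(
    gt: SequenceAnnotations,
    meta: SequenceMeta | None = None,
    teleport_body_lengths: float = TELEPORT_BODY_LENGTHS,
) -> list[QCIssue]:
    """Frame-level integrity checks; returns a deterministic issue list.

    Image-bound and teleport checks need ``meta`` (resolution, body-length
    pixel calibration) and are omitted when it is absent.
    """
    if gt.role != GROUND_TRUTH:
        raise ValueError("qc checks apply to ground-truth annotations")
    issues: list[QCIssue] = []

    pair_counts = Counter((r.frame, r.track_id) for r in gt)
    for (frame, tid), count in sorted(pair_counts.items()):
        if count > 1:
            issues.append(
                QCIssue("error", "duplicate_pair", frame, tid, f"{count} records for this (frame, id)")
            )

    for r in sorted(gt, key=lambda r: (r.frame, r.track_id)):
        if r.width <= 0 or r.height <= 0:
            issues.append(
                QCIssue("error", "nonpositive_box", r.frame, r.track_id,
                        f"box {r.width} x {r.height}")
            )
        if r.confidence not in (0.0, 1.0):
            issues.append(
                QCIssue("error", "bad_confidence", r.frame, r.track_id,
                        f"ground-truth confidence flag must be 0 or 1, got {r.confidence}")
            )
        if meta is not None:
            w, h = meta.resolution
            cx, cy = r.center
            if not (0 <= cx < w and 0 <= cy < h):
                issues.append(
                    QCIssue("warning", "out_of_frame", r.frame, r.track_id,
                            f"box centre ({cx}, {cy}) outside {w} x {h} image")
                )

    for tid in gt.track_ids:
        track = gt.by_track(tid)
        frames = [r.frame for r in track]
        for prev, cur in zip(track, track[1:]):
            if cur.frame > prev.frame + 1:
                issues.append(
                    QCIssue("warning", "id_gap", prev.frame + 1, tid,
                            f"track absent for frames {prev.frame + 1}-{cur.frame - 1}")
                )
        if meta is not None and meta.body_length_px:
            limit = teleport_body_lengths * meta.body_length_px
            for prev, cur in zip(track, track[1:]):
                if cur.frame != prev.frame + 1:
                    continue
                d = math.dist(prev.center, cur.center)
                if d > limit:
                    issues.append(
                        QCIssue("warning", "teleport", cur.frame, tid,
                                f"moved {d:.1f} px in one frame (> {limit:.1f})")
                    )
        del frames
    issues.sort(key=lambda i: (i.frame, i.track_id, i.kind))
    return issues


def summarize(gt: SequenceAnnotations) -> SequenceSummary:
    """Coarse sequence-level counts, invariant under record permutation."""
    per_frame = Counter(r.frame for r in gt)
    return SequenceSummary(
        n_frames_annotated=len(per_frame),
        n_tracks=len(gt.track_ids),
        n_records=len(gt),
        records_per_frame=dict(sorted(per_frame.items())),
    )


def manifest_totals(manifest: Mapping[str, SequenceMeta] | Iterable[SequenceMeta]) -> tuple[int, int]:
    """Column sums over a manifest: (total frames, total ants)."""
    metas = manifest.values() if isinstance(manifest, Mapping) else manifest
    metas = list(metas)
    return (sum(m.n_frames for m in metas), sum(m.n_ants for m in metas))


def segment_report(issues: Sequence[QCIssue], window: int = 5) -> list[tuple[int, int]]:
    """Frame segments needing remarking, from error-severity issues.

    Error frames closer than ``window`` frames apart are clustered into one
    segment; each segment is reported as an inclusive (first, last) frame
    pair.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frames = sorted({i.frame for i in issues if i.severity == "error"})
    if not frames:
        return []
    segments: list[tuple[int, int]] = []
    start = prev = frames[0]
    for f in frames[1:]:
        if f - prev > window:
            segments.append((start, prev))
            start = f
        prev = f
    segments.append((start, prev))
    return segments
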