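"""Trajectory speed analysis: pixel displacement, body-length calibration, speeds.

The pixel displacement of an ant between adjacent frames is the Euclidean
distance of its box centres,

    d_t = sqrt((x_t - x_{t-1})^2 + (y_t - y_{t-1})^2)    [pixels],

which is converted to the real world by the body-length calibration L/n (an
ant of true length L metres spans n pixels in the image) and to a speed by the
constant frame rate f_c:

    v_t = d_t * (L / n) * f_c    [m s^-1].

Each track's first frame is assigned speed 0 (the ant is assumed stationary at
the initial moment).  Displacement is only defined between adjacent frames;
across a gap in a track the speed is undefined, the missing frames are
recorded, and the track restarts at speed 0 on the first frame after the gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binned_statistic_2d

from .errors import DomainError, UndefinedStatisticError
from .mot_io import BoxRecord, SequenceAnnotations

__all__ = [
    "Calibration",
    "TrackPoint",
    "SpeedSeries",
    "SpeedSummary",
    "pixel_displacement",
    "speed",
    "track_speeds",
    "series_from_annotations",
    "summarize_speeds",
    "speed_histogram",
    "speed_heatmap",
    "speed_samples",
]

M_TO_CM = 100.0


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-world conversion: body length in metres (L) and pixels (n), frame rate."""

    body_length_m: float
    body_length_px: float
    fps: float

    def __post_init__(self) -> None:
        if self.body_length_m <= 0 or self.body_length_px <= 0 or self.fps <= 0:
            raise DomainError("calibration values must be strictly positive")

    @property
    def m_per_px(self) -> float:
        return self.body_length_m / self.body_length_px


@dataclass(frozen=True)
class TrackPoint:
    """An ant's position at one frame: the centre of its bounding box."""

    frame: int
    px: float
    py: float

    @classmethod
    def from_record(cls, rec: BoxRecord) -> "TrackPoint":
        cx, cy = rec.center
        return cls(rec.frame, cx, cy)


@dataclass
class SpeedSeries:
    """Per-frame speeds of one track, in m/s; ``gaps`` lists frames with no record."""

    track_id: int
    entries: list[tuple[int, float]]
    gaps: list[int]

    @property
    def speeds(self) -> np.ndarray:
        return np.array([v for _, v in self.entries], dtype=float)


@dataclass(frozen=True)
class SpeedSummary:
    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def pixel_displacement(p_t: TrackPoint, p_prev: TrackPoint) -> float:
    """Euclidean pixel distance between an ant's centres on adjacent frames."""
    if p_t.frame != p_prev.frame + 1:
        raise DomainError(
            f"displacement needs adjacent frames, got {p_prev.frame} -> {p_t.frame}"
        )
    return float(np.hypot(p_t.px - p_prev.px, p_t.py - p_prev.py))


def speed(displacement_px: float, calib: Calibration) -> float:
    """Convert a one-frame pixel displacement to a speed in m/s."""
    return displacement_px * calib.m_per_px * calib.fps


def track_speeds(points: Sequence[TrackPoint], calib: Calibration, track_id: int = 0) -> SpeedSeries:
    """Per-frame speed series of one track.

    ``points`` must be sorted by frame.  The first frame (and the first frame
    after every gap) gets speed 0; frames missing from the track are listed in
    ``gaps``.
    """
    frames = [p.frame for p in points]
    if frames != sorted(frames) or len(set(frames)) != len(frames):
        raise DomainError("track points must be sorted by frame, without duplicates")
    entries: list[tuple[int, float]] = []
    gaps: list[int] = []
    for i, p in enumerate(points):
        if i == 0 or p.frame != points[i - 1].frame + 1:
            entries.append((p.frame, 0.0))
            if i > 0:
                gaps.extend(range(points[i - 1].frame + 1, p.frame))
        else:
            entries.append((p.frame, speed(pixel_displacement(p, points[i - 1]), calib)))
    return SpeedSeries(track_id=track_id, entries=entries, gaps=gaps)


def series_from_annotations(gt: SequenceAnnotations, calib: Calibration) -> list[SpeedSeries]:
    """One :class:`SpeedSeries` per track in a ground-truth collection.

    Records with confidence flag 0 ("do not consider") are excluded.
    """
    out = []
    for tid in gt.track_ids:
        track = [TrackPoint.from_record(r) for r in gt.by_track(tid) if r.confidence != 0]
        if track:
            out.append(track_speeds(track, calib, track_id=tid))
    return out


def _pooled_cm_s(series: Iterable[SpeedSeries]) -> np.ndarray:
    arrays = [s.speeds for s in series]
    if not arrays:
        return np.array([])
    return np.concatenate(arrays) * M_TO_CM


def summarize_speeds(series: Iterable[SpeedSeries]) -> SpeedSummary:
    """Pooled mean +/- population SD over every (track, frame) speed, in cm/s.

    Pools all per-frame speeds from all tracks, including the forced zeros at
    track starts; the SD divisor is N (a census of frames, not a sample).
    """
    pooled = _pooled_cm_s(series)
    if pooled.size == 0:
        raise UndefinedStatisticError("no speed entries to summarise")
    return SpeedSummary(mean=float(pooled.mean()), sd=float(pooled.std()), n=int(pooled.size))


def per_track_means(series: Iterable[SpeedSeries]) -> dict[int, float]:
    """Alternative pooling: mean speed per track, in cm/s."""
    return {s.track_id: float(s.speeds.mean() * M_TO_CM) for s in series if s.entries}


def speed_histogram(
    series: Iterable[SpeedSeries], bin_width_cm_s: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Binned speed frequencies in cm/s; returns (counts, bin_edges).

    Total histogram mass equals the number of speed entries.
    """
    if bin_width_cm_s <= 0:
        raise DomainError("bin width must be > 0")
    pooled = _pooled_cm_s(series)
    if pooled.size == 0:
        raise UndefinedStatisticError("no speed entries to histogram")
    n_bins = max(1, int(np.ceil((pooled.max() + 1e-12) / bin_width_cm_s)))
    edges = np.arange(n_bins + 1) * bin_width_cm_s
    counts, edges = np.histogram(pooled, bins=edges)
    return counts, edges


def speed_samples(gt: SequenceAnnotations, calib: Calibration) -> np.ndarray:
    """(x, y, v_cm_s) samples pairing each speed entry with its image position."""
    rows = []
    for tid in gt.track_ids:
        track = [TrackPoint.from_record(r) for r in gt.by_track(tid) if r.confidence != 0]
        if not track:
            continue
        series = track_speeds(track, calib, track_id=tid)
        by_frame = {p.frame: p for p in track}
        for frame, v in series.entries:
            p = by_frame[frame]
            rows.append((p.px, p.py, v * M_TO_CM))
    return np.array(rows, dtype=float).reshape(-1, 3)


def speed_heatmap(
    samples: np.ndarray,
    grid: tuple[int, int],
    image_size: tuple[int, int],
) -> np.ndarray:
    """Mean speed per spatial cell over the image, shape (rows, cols).

    ``samples`` holds (x, y, v) rows as produced by :func:`speed_samples`.
    Cells with no samples are NaN.  Cell means are bounded by the min/max of
    their contributing speeds.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise DomainError("grid dimensions must be >= 1")
    w, h = image_size
    samples = np.asarray(samples, dtype=float).reshape(-1, 3)
    if samples.shape[0] == 0:
        return np.full((rows, cols), np.nan)
    stat, _, _, _ = binned_statistic_2d(
        samples[:, 0],
        samples[:, 1],
        samples[:, 2],
        statistic="mean",
        bins=[cols, rows],
        range=[[0, w], [0, h]],
    )
    return stat.T  # (rows, cols), row 0 at the image top
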