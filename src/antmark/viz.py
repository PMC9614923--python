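"""Visual verification outputs: trajectory overlays, speed heatmaps, histograms.

These are the three standard data-quality figures for a marked sequence: the
trajectories drawn on the original frames, the mean-speed field over image
space, and the frequency histogram of speeds in cm/s.  Everything here is a
thin rendering layer over :mod:`antmark.kinematics`; all renders are
deterministic for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import kinematics, mot_io
from .errors import DomainError
from .kinematics import Calibration, SpeedSeries
from .mot_io import SequenceAnnotations

__all__ = ["RenderSpec", "PALETTE", "track_color", "render_overlay", "render_speed_figures"]

#: fixed qualitative palette; track colors are stable across runs
PALETTE: tuple[tuple[int, int, int], ...] = (
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
)


def track_color(track_id: int) -> tuple[int, int, int]:
    """Deterministic id -> color mapping into the fixed palette."""
    return PALETTE[track_id % len(PALETTE)]


@dataclass(frozen=True)
class RenderSpec:
    """Options for the visual outputs."""

    output_dir: Path
    trail_length: int | None = None  # None = full history
    show_ids: bool = True
    heatmap_grid: tuple[int, int] = (36, 64)  # (rows, cols)
    bin_width_cm_s: float = 0.25

    def __post_init__(self) -> None:
        if self.trail_length is not None and self.trail_length < 1:
            raise DomainError("trail length must be >= 1")
        if self.heatmap_grid[0] < 1 or self.heatmap_grid[1] < 1:
            raise DomainError("heatmap grid dimensions must be >= 1")
        if self.bin_width_cm_s <= 0:
            raise DomainError("histogram bin width must be > 0")


def render_overlay(
    img_dir: str | Path,
    gt: SequenceAnnotations,
    spec: RenderSpec,
) -> list[Path]:
    """Draw per-track boxes and trailing polylines onto each frame.

    Output images keep the input dimensions; each present track is drawn in
    its palette color with the trajectory up to that frame (truncated to
    ``trail_length`` when set).
    """
    from PIL import Image, ImageDraw

    img_dir = Path(img_dir)
    out_dir = Path(spec.output_dir)
    if out_dir.resolve() == img_dir.resolve():
        raise DomainError("output directory must differ from the input directory")
    out_dir.mkdir(parents=True, exist_ok=True)

    history: dict[int, list[tuple[float, float]]] = {}
    paths: list[Path] = []
    for frame in gt.frames:
        src = img_dir / mot_io.frame_filename(frame)
        if not src.exists():
            raise FileNotFoundError(f"missing frame file {src}")
        img = Image.open(src).convert("RGB")
        draw = ImageDraw.Draw(img)
        for rec in sorted(gt.by_frame(frame), key=lambda r: r.track_id):
            color = track_color(rec.track_id)
            history.setdefault(rec.track_id, []).append(rec.center)
            trail = history[rec.track_id]
            if spec.trail_length is not None:
                trail = trail[-spec.trail_length:]
            if len(trail) > 1:
                draw.line(trail, fill=color, width=2)
            draw.rectangle(
                [rec.left, rec.top, rec.left + rec.width, rec.top + rec.height],
                outline=color, width=2,
            )
            if spec.show_ids:
                draw.text((rec.left, rec.top - 12), str(rec.track_id), fill=color)
        dst = out_dir / mot_io.frame_filename(frame)
        img.save(dst, quality=95)
        paths.append(dst)
    return paths


def render_speed_figures(
    series: Sequence[SpeedSeries],
    gt: SequenceAnnotations,
    calib: Calibration,
    image_size: tuple[int, int],
    spec: RenderSpec,
) -> dict[str, Path]:
    """Speed heatmap + histogram images and a tabular export.

    Returns paths keyed ``heatmap`` / ``histogram`` / ``table``.  The
    histogram bar mass equals the number of speed entries; the heatmap shows
    the mean speed per image-space cell with no-data cells neutral.
    """
    out_dir = Path(spec.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    counts, edges = kinematics.speed_histogram(series, spec.bin_width_cm_s)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="#4878a8", edgecolor="white")
    ax.set_xlabel("speed (cm/s)")
    ax.set_ylabel("frequency")
    hist_path = out_dir / "speed_histogram.png"
    fig.savefig(hist_path, dpi=120)
    plt.close(fig)

    samples = kinematics.speed_samples(gt, calib)
    field = kinematics.speed_heatmap(samples, spec.heatmap_grid, image_size)
    fig, ax = plt.subplots(figsize=(6, 4))
    masked = np.ma.masked_invalid(field)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("#dddddd")
    im = ax.imshow(masked, cmap=cmap, origin="upper",
                   extent=(0, image_size[0], image_size[1], 0), aspect="auto")
    fig.colorbar(im, ax=ax, label="mean speed (cm/s)")
    heat_path = out_dir / "speed_heatmap.png"
    fig.savefig(heat_path, dpi=120)
    plt.close(fig)

    rows = [
        {"frame": frame, "track_id": s.track_id, "speed_cm_s": v * kinematics.M_TO_CM}
        for s in series
        for frame, v in s.entries
    ]
    table_path = out_dir / "speeds.csv"
    pd.DataFrame(rows, columns=["frame", "track_id", "speed_cm_s"]).to_csv(
        table_path, index=False
    )
    return {"heatmap": heat_path, "histogram": hist_path, "table": table_path}
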