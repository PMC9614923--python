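"""Seeded synthetic colony-motion generator.

Generates ground-truth trajectories with the statistical structure of the
filmed sequences so that every other module is testable without the video
deposit.  Two regimes:

``indoor``
    A fixed roster of ants, all present in every frame, moving inside a
    bounded arena with reflecting walls (record count = n_ants * n_frames).

``outdoor``
    Ants enter the scene near a nest entrance over the course of the
    sequence and leave when they wander off the image (absorbing boundary);
    IDs are assigned in spawn order and never reused.

The motion model is a correlated random walk: each ant keeps a heading that
diffuses by a wrapped-normal increment whose concentration is set by the
``heading_persistence`` parameter rho = E[cos(delta_theta)], takes
Gamma-distributed step lengths, and pauses (step 0) with probability
``pause_prob`` per frame.  The Gamma mean is chosen so that the expected
per-frame speed — through the same pixel-displacement / body-length /
frame-rate conversion the analysis applies — equals ``mean_speed_cm_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


import numpy as np

from . import mot_io
from .errors import DomainError
from .mot_io import DETECTION, GROUND_TRUTH, BoxRecord, SequenceAnnotations

__all__ = ["SimConfig", "SimOutput", "simulate_colony", "degrade_to_detections",
           "render_frames", "write_sequence_dir"]

M_TO_CM = 100.0


@dataclass(frozen=True)
class SimConfig:
    """Colony-simulation parameters.

    Defaults mirror an indoor laboratory sequence: 10 ants over 351 frames at
    25 fps in a 1920 x 1080 image, ants of 10.6 mm spanning ~120 px, marked
    with 94 x 94 boxes, and a mean speed of 2.16 cm/s.
    """

    n_ants: int = 10
    n_frames: int = 351
    fps: float = 25.0
    image_size: tuple[int, int] = (1920, 1080)
    mode: str = "indoor"
    nest_point: tuple[float, float] | None = None
    mean_speed_cm_s: float = 2.16
    heading_persistence: float = 0.9
    pause_prob: float = 0.1
    step_shape: float = 4.0
    body_length_px: float = 120.0
    body_length_m: float = 0.0106
    box_size: int = 94
    seq_label: str = "0001"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 0 or self.n_frames < 1:
            raise DomainError("n_ants must be >= 0 and n_frames >= 1")
        if self.fps <= 0 or self.body_length_px <= 0 or self.body_length_m <= 0:
            raise DomainError("fps and body lengths must be strictly positive")
        if self.mode not in ("indoor", "outdoor"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.mode == "outdoor" and self.nest_point is None:
            raise DomainError("outdoor mode requires a nest_point")
        if not (0 <= self.heading_persistence < 1):
            raise DomainError("heading_persistence must lie in [0, 1)")
        if not (0 <= self.pause_prob < 1):
            raise DomainError("pause_prob must lie in [0, 1)")
        if self.mean_speed_cm_s < 0 or self.box_size <= 0:
            raise DomainError("mean speed must be >= 0 and box size > 0")

    @classmethod
    def outdoor(cls, **overrides) -> "SimConfig":
        """Outdoor preset mirroring a nest-entrance sequence (73 ants, 600
        frames, 30 fps, 1280 x 720, 9 mm ants spanning ~68 px, 1.98 cm/s)."""
        base = dict(
            n_ants=73, n_frames=600, fps=30.0, image_size=(1280, 720),
            mode="outdoor", nest_point=(640.0, 360.0), mean_speed_cm_s=1.98,
            body_length_px=68.0, body_length_m=0.009, box_size=50,
            seq_label="0006",
        )
        base.update(overrides)
        return cls(**base)

    @property
    def cm_per_px(self) -> float:
        return self.body_length_m * M_TO_CM / self.body_length_px

    @property
    def mean_step_px(self) -> float:
        """Gamma mean of moving steps so the per-frame expected speed matches."""
        per_frame_cm = self.mean_speed_cm_s / self.fps
        return per_frame_cm / self.cm_per_px / (1.0 - self.pause_prob)

    @property
    def image_set_name(self) -> mot_io.ImageSetName:
        first = self.n_ants if self.mode == "indoor" else self._n_initial
        return mot_io.ImageSetName(self.seq_label, first, self.box_size)

    @property
    def _n_initial(self) -> int:
        if self.mode == "indoor" or self.n_ants == 0:
            return self.n_ants
        return max(1, round(0.3 * self.n_ants))


@dataclass
class SimOutput:
    """Ground truth plus the generator's own record of true motion."""

    gt: SequenceAnnotations
    truth_speeds: dict[int, np.ndarray]           # per track, cm/s, first entry 0
    centers: dict[int, list[tuple[int, float, float]]]  # per track (frame, x, y)
    config: SimConfig

    @property
    def pooled_truth_speeds(self) -> np.ndarray:
        if not self.truth_speeds:
            return np.array([])
        return np.concatenate(list(self.truth_speeds.values()))


def _heading_sd(rho: float) -> float:
    # wrapped-normal concentration: rho = E[cos dtheta] = exp(-sd^2 / 2)
    if rho == 0:
        return math.pi  # effectively uncorrelated
    return math.sqrt(-2.0 * math.log(rho))


def _walk(
    rng: np.random.Generator,
    config: SimConfig,
    start: np.ndarray,
    n_steps: int,
    absorbing: bool,
) -> np.ndarray:
    """Positions of one ant over up to ``n_steps + 1`` frames.

    Indoor walls deflect: a step that would leave the arena keeps its length
    and re-draws its heading until it stays inside (ants turn at walls), so
    wall interactions do not bias the step-length — and hence the measured
    speed — distribution.  With ``absorbing`` the walk instead stops at the
    first position outside the image (that position is not included).
    """
    w, h = config.image_size
    sd = _heading_sd(config.heading_persistence)
    scale = config.mean_step_px / config.step_shape
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pos = [start.copy()]
    cur = start.copy()
    for _ in range(n_steps):
        theta += rng.normal(0.0, sd)
        if rng.uniform() < config.pause_prob:
            step = 0.0
        else:
            step = rng.gamma(config.step_shape, scale)
        nxt = cur + step * np.array([math.cos(theta), math.sin(theta)])
        if absorbing:
            if not (0 <= nxt[0] <= w and 0 <= nxt[1] <= h):
                break
        else:
            for attempt in range(64):
                if 0 <= nxt[0] <= w and 0 <= nxt[1] <= h:
                    break
                # turn rather than shorten: wider and wider heading re-draws
                theta += rng.normal(0.0, sd * (1 + attempt))
                nxt = cur + step * np.array([math.cos(theta), math.sin(theta)])
            else:  # step longer than any inside direction: clamp (degenerate arena)
                nxt = np.clip(nxt, [0, 0], [w, h])
        cur = nxt
        pos.append(cur.copy())
    return np.array(pos)


def _speeds_cm_s(path: np.ndarray, config: SimConfig) -> np.ndarray:
    d = np.hypot(np.diff(path[:, 0]), np.diff(path[:, 1]))
    v = d * config.cm_per_px * config.fps
    return np.concatenate([[0.0], v])


def simulate_colony(config: SimConfig) -> SimOutput:
    """Generate one synthetic sequence; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    w, h = config.image_size
    records: list[BoxRecord] = []
    truth_speeds: dict[int, np.ndarray] = {}
    centers: dict[int, list[tuple[int, float, float]]] = {}

    if config.mode == "indoor":
        spawn = [(1, None) for _ in range(config.n_ants)]
    else:
        n0 = config._n_initial
        n_later = config.n_ants - n0
        later = np.sort(rng.integers(2, config.n_frames + 1, size=n_later)) if (
            n_later > 0 and config.n_frames >= 2
        ) else np.array([], dtype=int)
        spawn = [(1, "nest") for _ in range(n0)] + [(int(f), "nest") for f in later]

    for idx, (start_frame, origin) in enumerate(spawn):
        track_id = idx + 1
        if origin is None:
            start = rng.uniform([0.05 * w, 0.05 * h], [0.95 * w, 0.95 * h])
        else:
            nest = np.asarray(config.nest_point, dtype=float)
            start = nest + rng.normal(0.0, 2.0 * config.body_length_px, size=2)
            start = np.clip(start, [0, 0], [w, h])
        n_steps = config.n_frames - start_frame
        path = _walk(rng, config, start, n_steps, absorbing=(config.mode == "outdoor"))
        frames = range(start_frame, start_frame + len(path))
        centers[track_id] = [(f, float(x), float(y)) for f, (x, y) in zip(frames, path)]
        truth_speeds[track_id] = _speeds_cm_s(path, config)
        for f, (x, y) in zip(frames, path):
            records.append(
                BoxRecord.from_center(f, track_id, float(x), float(y), config.box_size)
            )

    gt = SequenceAnnotations(
        sequence_id=config.seq_label, role=GROUND_TRUTH, records=records
    )
    gt.records = gt.sorted_records()
    return SimOutput(gt=gt, truth_speeds=truth_speeds, centers=centers, config=config)


def degrade_to_detections(
    gt: SequenceAnnotations,
    jitter_sd: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] | None = None,
) -> SequenceAnnotations:
    """Turn ground truth into a detection file: IDs -1, confidence 1.

    Positions are jittered by integer-rounded Gaussian noise of ``jitter_sd``
    pixels, records are dropped independently with probability ``fn_rate``,
    and a spurious box is added per frame with probability ``fp_rate``.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise DomainError("fp_rate and fn_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = [r.width for r in gt] or [50.0]
    med_size = float(np.median(sizes))
    if image_size is None:
        max_x = max((r.left + r.width for r in gt), default=1000.0)
        max_y = max((r.top + r.height for r in gt), default=1000.0)
        image_size = (int(max_x), int(max_y))
    out: list[BoxRecord] = []
    for r in gt.sorted_records():
        if rng.uniform() < fn_rate:
            continue
        dx = dy = 0.0
        if jitter_sd > 0:
            dx, dy = np.round(rng.normal(0.0, jitter_sd, size=2))
        out.append(BoxRecord(r.frame, -1, r.left + dx, r.top + dy, r.width, r.height, 1.0))
    frames = gt.frames or [1]
    for f in frames:
        if rng.uniform() < fp_rate:
            x = rng.uniform(0, image_size[0])
            y = rng.uniform(0, image_size[1])
            out.append(
                BoxRecord.from_center(f, -1, x, y, int(med_size), confidence=1.0)
            )
    det = SequenceAnnotations(sequence_id=gt.sequence_id, role=DETECTION, records=out)
    det.records = det.sorted_records()
    return det


def _ellipse_polygon(cx: float, cy: float, theta: float, length: float, width: float,
                     n_vertices: int = 24) -> list[tuple[float, float]]:
    t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    ex = (length / 2) * np.cos(t)
    ey = (width / 2) * np.sin(t)
    c, s = math.cos(theta), math.sin(theta)
    return [(cx + c * x - s * y, cy + s * x + c * y) for x, y in zip(ex, ey)]


def render_frames(
    gt: SequenceAnnotations,
    config: SimConfig,
    out_dir: str | Path,
    quality: int = 95,
) -> list[Path]:
    """Render one JPEG per frame with each ant as an oriented dark ellipse.

    Blob length is about one body length; orientation follows the track's
    local direction of motion.  Outdoor mode adds seeded background texture.
    Frames are named ``000001.jpg`` onward.
    """
    from PIL import Image, ImageDraw

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w, h = config.image_size
    rng = np.random.default_rng(config.seed + 1)

    tracks = {tid: gt.by_track(tid) for tid in gt.track_ids}
    headings: dict[tuple[int, int], float] = {}
    for tid, recs in tracks.items():
        for prev, cur in zip(recs, recs[1:]):
            (x0, y0), (x1, y1) = prev.center, cur.center
            ang = math.atan2(y1 - y0, x1 - x0) if (x1, y1) != (x0, y0) else headings.get(
                (tid, prev.frame), 0.0
            )
            headings[(tid, cur.frame)] = ang
            headings.setdefault((tid, prev.frame), ang)

    paths: list[Path] = []
    n_frames = config.n_frames
    for f in range(1, n_frames + 1):
        if config.mode == "outdoor":
            base = rng.integers(185, 215, size=(h, w), dtype=np.uint8)
            arr = np.repeat(base[:, :, None], 3, axis=2)
            img = Image.fromarray(arr, "RGB")
        else:
            img = Image.new("RGB", (w, h), (225, 222, 216))
        draw = ImageDraw.Draw(img)
        for r in gt.by_frame(f):
            cx, cy = r.center
            theta = headings.get((r.track_id, f), 0.0)
            poly = _ellipse_polygon(cx, cy, theta, config.body_length_px,
                                    config.body_length_px / 3.0)
            draw.polygon(poly, fill=(35, 28, 22))
        path = out_dir / mot_io.frame_filename(f)
        img.save(path, quality=quality)
        paths.append(path)
    return paths


def write_sequence_dir(
    output: SimOutput,
    root: str | Path,
    render: bool = False,
) -> Path:
    """Emit a complete sequence directory: img/ (optional), gt/gt.txt, det/det.txt.

    The directory is named with the image-set grammar so it can be opened by
    an annotation session.
    """
    config = output.config
    seq_dir = Path(root) / str(config.image_set_name)
    (seq_dir / "gt").mkdir(parents=True, exist_ok=True)
    (seq_dir / "det").mkdir(parents=True, exist_ok=True)
    mot_io.write_annotations(output.gt, seq_dir / "gt" / "gt.txt")
    det = degrade_to_detections(output.gt, seed=config.seed)
    mot_io.write_annotations(det, seq_dir / "det" / "det.txt")
    if render:
        render_frames(output.gt, config, seq_dir / "img")
    else:
        (seq_dir / "img").mkdir(exist_ok=True)
    return seq_dir
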