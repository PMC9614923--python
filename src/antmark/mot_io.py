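"""Reading and writing the MOT-dialect annotation format and sequence metadata.

Each image sequence in an ant-colony tracking dataset is organised as a folder
triple ``det/``, ``gt/``, ``img/``.  The ``det.txt`` and ``gt.txt`` files use
the MOTChallenge text dialect: one comma-separated line per object instance
with seven numeric fields::

    frame, id, bb_left, bb_top, bb_width, bb_height, confidence

Ground-truth lines carry a real track ID (>= 1) and a 0/1 confidence flag
("whether the entry is to be considered"); detection lines carry ID -1 and a
detector score.  Pixel coordinates are 0-based with the origin at the image's
top-left corner, x rightward and y downward; ``left``/``top`` denote the box's
top-left corner.  Frame indices are 1-based, matching image file names such as
``000001.jpg``.

The reader enforces line shape, numeric fields and the role's ID invariant,
and rejects duplicate ``(frame, id)`` pairs in the ground-truth role.  Box
positivity and confidence-flag violations are representable in memory on
purpose, so that :mod:`antmark.qc` can report them as issues instead of the
loader refusing the file outright.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping

import yaml

from .errors import DomainError, FormatError, IntegrityError, ParseError

__all__ = [
    "DETECTION",
    "GROUND_TRUTH",
    "Role",
    "BoxRecord",
    "SequenceAnnotations",
    "ImageSetName",
    "SequenceMeta",
    "read_annotations",
    "write_annotations",
    "parse_image_set_name",
    "frame_filename",
    "load_manifest",
    "builtin_manifest",
]

DETECTION = "detection"
GROUND_TRUTH = "ground_truth"
Role = Literal["detection", "ground_truth"]

_N_FIELDS = 7
_IMAGE_SET_RE = re.compile(r"^Seq(?P<x>.+?)Object(?P<y>\d+)Image(?P<z>\d+)$")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (52.5 -> 53)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class BoxRecord:
    """One annotation or detection line.

    ``track_id`` is >= 1 in the ground-truth role and exactly -1 in the
    detection role.  ``confidence`` is a detector score for detections and a
    0/1 consider-flag for ground truth.
    """

    frame: int
    track_id: int
    left: float
    top: float
    width: float
    height: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise DomainError(f"frame index must be >= 1, got {self.frame}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)

    @classmethod
    def from_center(
        cls,
        frame: int,
        track_id: int,
        cx: float,
        cy: float,
        box_size: int,
        confidence: float = 1.0,
    ) -> "BoxRecord":
        """Square box of side ``box_size`` centred on a click point.

        Corners are rounded half-away-from-zero to integer pixels, so an odd
        side splits asymmetrically (side 95, click x=100 -> left 53).
        """
        return cls(
            frame=frame,
            track_id=track_id,
            left=round_half_away(cx - box_size / 2.0),
            top=round_half_away(cy - box_size / 2.0),
            width=box_size,
            height=box_size,
            confidence=confidence,
        )


def _validate_role(rec: BoxRecord, role: Role, where: str = "") -> None:
    if role == DETECTION and rec.track_id != -1:
        raise IntegrityError(f"detection record must have id -1{where}, got {rec.track_id}")
    if role == GROUND_TRUTH and rec.track_id < 1:
        raise IntegrityError(f"ground-truth record must have id >= 1{where}, got {rec.track_id}")


@dataclass
class SequenceAnnotations:
    """All det- or gt-role records of one sequence, indexable by frame and track.

    Construction enforces the role's ID invariant and, in the ground-truth
    role, uniqueness of ``(frame, id)`` pairs.  ``validate=False`` skips both,
    so that qc can inspect deliberately broken collections.
    """

    sequence_id: str
    role: Role
    records: list[BoxRecord] = field(default_factory=list)
    validate: bool = True

    def __post_init__(self) -> None:
        if self.role not in (DETECTION, GROUND_TRUTH):
            raise DomainError(f"unknown role {self.role!r}")
        if not self.validate:
            return
        for rec in self.records:
            _validate_role(rec, self.role)
        if self.role == GROUND_TRUTH:
            dupes = [k for k, c in Counter((r.frame, r.track_id) for r in self.records).items() if c > 1]
            if dupes:
                raise IntegrityError(f"duplicate (frame, id) pairs in ground truth: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BoxRecord]:
        return iter(self.records)

    @property
    def frames(self) -> list[int]:
        return sorted({r.frame for r in self.records})

    @property
    def track_ids(self) -> list[int]:
        return sorted({r.track_id for r in self.records})

    def by_frame(self, frame: int) -> list[BoxRecord]:
        return [r for r in self.records if r.frame == frame]

    def by_track(self, track_id: int) -> list[BoxRecord]:
        return sorted((r for r in self.records if r.track_id == track_id), key=lambda r: r.frame)

    def sorted_records(self) -> list[BoxRecord]:
        """Records in canonical serialisation order: frame ascending, then id."""
        return sorted(self.records, key=lambda r: (r.frame, r.track_id))


def _fmt_number(x: float) -> str:
    """Integers without a decimal point; reals via the shortest round-trip repr."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _parse_line(line: str, lineno: int) -> BoxRecord:
    parts = line.split(",")
    if len(parts) != _N_FIELDS:
        raise ParseError(f"line {lineno}: expected {_N_FIELDS} comma-separated fields, got {len(parts)}")
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    frame, track_id = values[0], values[1]
    if not frame.is_integer() or not track_id.is_integer():
        raise ParseError(f"line {lineno}: frame and id must be integers")
    try:
        return BoxRecord(int(frame), int(track_id), values[2], values[3], values[4], values[5], values[6])
    except DomainError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def read_annotations(path: str | Path, role: Role, sequence_id: str | None = None) -> SequenceAnnotations:
    """Parse a det.txt / gt.txt file.

    Input order is preserved in memory.  Malformed lines raise
    :class:`~antmark.errors.ParseError` naming the 1-based line number; a
    duplicate ``(frame, id)`` pair in the ground-truth role raises
    :class:`~antmark.errors.IntegrityError`.
    """
    path = Path(path)
    records: list[BoxRecord] = []
    text = path.read_text()
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.rstrip("\r").strip()
        if not line:
            continue
        rec = _parse_line(line, lineno)
        _validate_role(rec, role, where=f" (line {lineno})")
        records.append(rec)
    seq_id = sequence_id if sequence_id is not None else path.stem
    return SequenceAnnotations(sequence_id=seq_id, role=role, records=records)


def write_annotations(seq: SequenceAnnotations, path: str | Path) -> None:
    """Serialise sorted by (frame, id), comma-separated, ``\\n`` line ends."""
    path = Path(path)
    lines = []
    for r in seq.sorted_records():
        fields = (r.frame, r.track_id, r.left, r.top, r.width, r.height, r.confidence)
        lines.append(",".join(_fmt_number(v) for v in fields))
    path.write_text("".join(line + "\n" for line in lines))


@dataclass(frozen=True)
class ImageSetName:
    """Folder-name grammar ``Seq{X}Object{Y}Image{Z}``.

    X labels the sequence, Y is the number of objects in the first frame and
    Z the side (pixels) of the square annotation box.
    """

    seq_label: str
    object_count: int
    box_size: int

    def __post_init__(self) -> None:
        if self.object_count < 0:
            raise DomainError("object_count must be >= 0")
        if self.box_size <= 0:
            raise DomainError("box_size must be > 0")

    def __str__(self) -> str:
        return f"Seq{self.seq_label}Object{self.object_count}Image{self.box_size}"


def parse_image_set_name(name: str) -> ImageSetName:
    """Decompose ``Seq0001Object10Image94`` into ("0001", 10, 94)."""
    m = _IMAGE_SET_RE.match(name)
    if m is None:
        raise FormatError(f"{name!r} does not match the SeqXObjectYImageZ grammar")
    return ImageSetName(m.group("x"), int(m.group("y")), int(m.group("z")))


def frame_filename(i: int) -> str:
    """Zero-padded 6-digit JPEG name for frame ``i`` (1 -> "000001.jpg")."""
    if i < 1:
        raise DomainError(f"frame index must be >= 1, got {i}")
    if i > 999_999:
        raise DomainError(f"frame index {i} exceeds the 6-digit naming scheme")
    return f"{i:06d}.jpg"


@dataclass(frozen=True)
class SequenceMeta:
    """Per-sequence filming metadata.

    ``tilt_angle_deg`` is the camera's horizontal-plane tilt; the view angles
    are the camera's printed horizontal/vertical angles of view.  The optional
    body-length pair calibrates pixels to metres (an ant of ``body_length_m``
    metres spans ``body_length_px`` pixels in the image).
    """

    sequence_id: str
    fps: float
    resolution: tuple[int, int]
    n_frames: int
    n_ants: int
    camera_height_cm: float
    tilt_angle_deg: float
    view_angle_h_deg: float = 16.0
    view_angle_v_deg: float = 7.5
    body_length_m: float | None = None
    body_length_px: float | None = None
    n_annotations: int | None = None
    species: str | None = None
    entrance: bool | None = None
    scene: str | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise DomainError(f"{self.sequence_id}: fps must be > 0")
        if self.camera_height_cm <= 0:
            raise DomainError(f"{self.sequence_id}: camera height must be > 0")
        if not (0 <= self.tilt_angle_deg < 90):
            raise DomainError(f"{self.sequence_id}: tilt angle must lie in [0, 90)")
        if self.view_angle_h_deg <= 0 or self.view_angle_v_deg <= 0:
            raise DomainError(f"{self.sequence_id}: view angles must be > 0")
        if self.resolution[0] <= 0 or self.resolution[1] <= 0:
            raise DomainError(f"{self.sequence_id}: resolution must be positive")
        if self.n_frames < 0 or self.n_ants < 0:
            raise DomainError(f"{self.sequence_id}: counts must be >= 0")

    @property
    def has_calibration(self) -> bool:
        return self.body_length_m is not None and self.body_length_px is not None


_REQUIRED_MANIFEST_KEYS = ("fps", "resolution", "length", "ants", "angle_deg", "height_cm")


def _meta_from_mapping(seq_id: str, entry: Mapping) -> SequenceMeta:
    missing = [k for k in _REQUIRED_MANIFEST_KEYS if k not in entry]
    if missing:
        raise ParseError(f"manifest entry {seq_id!r}: missing required fields {missing}")
    res = entry["resolution"]
    if not (isinstance(res, (list, tuple)) and len(res) == 2):
        raise ParseError(f"manifest entry {seq_id!r}: resolution must be a [width, height] pair")
    return SequenceMeta(
        sequence_id=seq_id,
        fps=float(entry["fps"]),
        resolution=(int(res[0]), int(res[1])),
        n_frames=int(entry["length"]),
        n_ants=int(entry["ants"]),
        camera_height_cm=float(entry["height_cm"]),
        tilt_angle_deg=float(entry["angle_deg"]),
        view_angle_h_deg=float(entry.get("view_angle_h_deg", 16.0)),
        view_angle_v_deg=float(entry.get("view_angle_v_deg", 7.5)),
        body_length_m=(None if entry.get("body_length_m") is None else float(entry["body_length_m"])),
        body_length_px=(None if entry.get("body_length_px") is None else float(entry["body_length_px"])),
        n_annotations=(None if entry.get("annotations") is None else int(entry["annotations"])),
        species=entry.get("species"),
        entrance=entry.get("entrance"),
        scene=entry.get("scene"),
    )


def load_manifest(path: str | Path) -> dict[str, SequenceMeta]:
    """Load a YAML manifest mapping sequence id -> filming metadata.

    Returns an insertion-ordered mapping; an empty manifest yields an empty
    mapping.  Missing required fields or invalid values raise.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, Mapping):
        raise ParseError("manifest must be a mapping of sequence id -> fields")
    return {str(seq_id): _meta_from_mapping(str(seq_id), entry) for seq_id, entry in raw.items()}


def builtin_manifest() -> dict[str, SequenceMeta]:
    """The bundled ten-sequence manifest of the ant-colony video collection."""
    from importlib import resources

    with resources.files("antmark.data").joinpath("table1.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    return {str(k): _meta_from_mapping(str(k), v) for k, v in raw.items()}
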