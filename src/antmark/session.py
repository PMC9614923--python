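"""Headless annotation session: the marking workflow as an event-driven state machine.

The workflow annotates one object per pass over an image sequence: the user
selects an image set (a folder named ``Seq{X}Object{Y}Image{Z}`` containing an
``img/`` folder of JPEG frames), an output directory and an object ID, then
clicks the centre of that object on every frame.  Each click stores the centre
and a square bounding box of side Z around it.  Moving to the next frame
displays the previous frame's mark as a reference dot; a frame can be rolled
back, re-entered and modified, or marked absent (our extension for objects
that leave the scene).  After every object has been marked, the per-object
files are merged into a single ground-truth file sorted by frame and then ID.

Any GUI is a thin frontend over :class:`AnnotationSession`: the session
exposes the current frame's image path and reference point, and accepts click
/ advance / rollback / absent / modify events.  The session persists the
object's annotation file after every mutating event, so a session can be
resumed halfway through (start frame 0 is the "begin at the first frame"
sentinel; a positive start frame resumes there with previously saved marks
loaded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import mot_io
from .errors import FormatError, IntegrityError, RangeError
from .mot_io import (
    GROUND_TRUTH,
    BoxRecord,
    ImageSetName,
    SequenceAnnotations,
    parse_image_set_name,
)

__all__ = ["ClickEvent", "AnnotationSession", "start_session", "replay", "merge"]


@dataclass(frozen=True)
class ClickEvent:
    """A pointer click on the centre of the current object."""

    frame: int
    x: float
    y: float


class AnnotationSession:
    """State machine for marking one object across an image sequence.

    Parameters
    ----------
    image_set_dir:
        Folder whose name parses as ``Seq{X}Object{Y}Image{Z}`` and which
        contains an ``img/`` folder of frames.
    output_dir:
        Root under which the per-object folder (zero-padded object ID) and
        its annotation file are written.
    object_id:
        User-chosen identity number, >= 1; any number is allowed as long as
        it is unique within the sequence (uniqueness is enforced at merge).
    start_frame:
        0 means "begin at the first frame"; a positive value positions the
        session at that frame, with previously saved marks loaded.
    """

    def __init__(
        self,
        image_set_dir: str | Path,
        output_dir: str | Path,
        object_id: int,
        start_frame: int = 0,
    ) -> None:
        image_set_dir = Path(image_set_dir)
        self.image_set: ImageSetName = parse_image_set_name(image_set_dir.name)
        self.img_dir = image_set_dir / "img"
        if not self.img_dir.is_dir():
            raise FormatError(f"{image_set_dir} has no img/ folder")
        if object_id < 1:
            raise IntegrityError(f"object id must be >= 1, got {object_id}")
        self.n_frames = len(sorted(self.img_dir.glob("*.jpg")))
        if self.n_frames == 0:
            raise FormatError(f"{self.img_dir} contains no frames")
        self.object_id = int(object_id)
        self.box_size = self.image_set.box_size
        self.output_dir = Path(output_dir) / f"{self.object_id:04d}"
        self.output_path = self.output_dir / "gt.txt"
        # centre click per frame; persisted boxes quantise this to integer corners
        self.marks: dict[int, tuple[float, float]] = {}
        self.last_notice: str | None = None
        if self.output_path.exists():
            self._load_marks()
        if start_frame == 0:
            start_frame = 1
        if not (1 <= start_frame <= self.n_frames):
            raise RangeError(
                f"start frame {start_frame} outside sequence of {self.n_frames} frames"
            )
        self.current_frame = start_frame

    # -- frontend contract -------------------------------------------------

    @property
    def current_frame_path(self) -> Path:
        return self.img_dir / mot_io.frame_filename(self.current_frame)

    @property
    def reference_point(self) -> tuple[float, float] | None:
        """Most recent mark before the current frame (the green reference dot).

        The latest mark is carried forward across unmarked frames.
        """
        earlier = [f for f in self.marks if f < self.current_frame]
        if not earlier:
            return None
        return self.marks[max(earlier)]

    # -- events ------------------------------------------------------------

    def mark_center(self, click: ClickEvent) -> BoxRecord:
        """Store the click as the object's centre on the current frame.

        A second mark on the same frame replaces the first.  Edge clicks are
        legal even when the box extends beyond the image (qc flags them).
        """
        if click.frame != self.current_frame:
            raise RangeError(
                f"click is for frame {click.frame} but session is at {self.current_frame}"
            )
        self.marks[click.frame] = (click.x, click.y)
        self._persist()
        return BoxRecord.from_center(
            click.frame, self.object_id, click.x, click.y, self.box_size
        )

    def advance(self) -> bool:
        """Move to the next frame; no-op with a notice at the last frame."""
        self.last_notice = None
        if self.current_frame >= self.n_frames:
            self.last_notice = "already at the last frame"
            return False
        self.current_frame += 1
        return True

    def rollback(self) -> bool:
        """Roll back one frame; no-op with a notice at the first frame."""
        self.last_notice = None
        if self.current_frame <= 1:
            self.last_notice = "already at the first frame"
            return False
        self.current_frame -= 1
        return True

    def mark_absent(self) -> None:
        """Record that the object is absent from the current frame."""
        self.marks.pop(self.current_frame, None)
        self._persist()

    def modify(self, frame: int, x: float, y: float) -> BoxRecord:
        """Replace (or create) the mark of an arbitrary frame."""
        if not (1 <= frame <= self.n_frames):
            raise RangeError(f"frame {frame} outside sequence of {self.n_frames} frames")
        self.marks[frame] = (x, y)
        self._persist()
        return BoxRecord.from_center(frame, self.object_id, x, y, self.box_size)

    # -- persistence -------------------------------------------------------

    def annotations(self) -> SequenceAnnotations:
        """The object's marks as ground-truth records (confidence 1)."""
        records = [
            BoxRecord.from_center(f, self.object_id, x, y, self.box_size)
            for f, (x, y) in sorted(self.marks.items())
        ]
        return SequenceAnnotations(
            sequence_id=self.image_set.seq_label, role=GROUND_TRUTH, records=records
        )

    def _persist(self) -> None:
        self.output_dir.mkdir(parents=True, exist_ok=True)
        mot_io.write_annotations(self.annotations(), self.output_path)

    def _load_marks(self) -> None:
        saved = mot_io.read_annotations(self.output_path, GROUND_TRUTH)
        for rec in saved:
            if rec.track_id != self.object_id:
                raise IntegrityError(
                    f"{self.output_path} contains id {rec.track_id}, expected {self.object_id}"
                )
            self.marks[rec.frame] = rec.center


def start_session(
    image_set_dir: str | Path,
    output_dir: str | Path,
    object_id: int,
    start_frame: int = 0,
) -> AnnotationSession:
    """Open (or resume) an annotation session for one object."""
    return AnnotationSession(image_set_dir, output_dir, object_id, start_frame)


def replay(session: AnnotationSession, events: Iterable[tuple]) -> AnnotationSession:
    """Apply an event log to a session.

    Events are tuples: ``("mark", x, y)``, ``("advance",)``, ``("rollback",)``,
    ``("absent",)`` and ``("modify", frame, x, y)``.  Replaying the same log on
    the same inputs is deterministic and produces identical output files.
    """
    for event in events:
        kind = event[0]
        if kind == "mark":
            session.mark_center(ClickEvent(session.current_frame, event[1], event[2]))
        elif kind == "advance":
            session.advance()
        elif kind == "rollback":
            session.rollback()
        elif kind == "absent":
            session.mark_absent()
        elif kind == "modify":
            session.modify(event[1], event[2], event[3])
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return session


def merge(
    per_object_dirs: Sequence[str | Path], sequence_id: str = "merged"
) -> SequenceAnnotations:
    """Merge per-object annotation files into one ground-truth collection.

    Records are sorted by frame ascending, then object ID ascending.  Object
    IDs are user-supplied, so uniqueness across directories is enforced here:
    the same ID appearing in two directories raises
    :class:`~antmark.errors.IntegrityError`.  The result is permutation
    invariant in the order the directories are supplied.
    """
    all_records: list[BoxRecord] = []
    seen_ids: dict[int, Path] = {}
    for d in per_object_dirs:
        d = Path(d)
        files = sorted(d.glob("*.txt"))
        if not files:
            raise FormatError(f"{d} contains no annotation file")
        ids_here: set[int] = set()
        for f in files:
            for rec in mot_io.read_annotations(f, GROUND_TRUTH):
                ids_here.add(rec.track_id)
                all_records.append(rec)
        for tid in ids_here:
            if tid in seen_ids:
                raise IntegrityError(
                    f"object id {tid} appears in both {seen_ids[tid]} and {d}"
                )
            seen_ids[tid] = d
    merged = SequenceAnnotations(sequence_id=sequence_id, role=GROUND_TRUTH, records=all_records)
    merged.records = merged.sorted_records()
    return merged
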